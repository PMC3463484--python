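"""Read-cleaning cascade for two small-RNA libraries.

Stages: size window -> contaminant removal -> collapsing to unique
sequences with per-library counts -> length-variant grouping.  Every
stage reports removed/retained totals so the full cascade bookkeeping
(reads in = reads out + reads removed, per library) can be reproduced.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .seqs import VALID_BASES, revcomp, to_dna


@dataclass
class PreprocessConfig:
    """Size window and contaminant-matching tolerance.

    The default window is 18-24 nt; ``contaminant_max_mismatch``
    substitutions are tolerated in the full-length containment match of a
    read against any contaminant sequence (either strand).
    """

    l_min: int = 18
    l_max: int = 24
    contaminant_max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not (15 <= self.l_min <= self.l_max <= 30):
            raise ValueError("size window must satisfy 15 <= l_min <= l_max <= 30")


@dataclass
class SmallReadSet:
    """Collapsed unique small-RNA sequences with per-library counts.

    ``counts`` maps sequence -> (count_leaf, count_bud); ``n_leaf`` and
    ``n_bud`` are the library totals of reads surviving the size window
    (the denominators for expression statistics downstream).
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_leaf: int = 0
    n_bud: int = 0

    def __len__(self) -> int:
        return len(self.counts)

    def total(self, library: int) -> int:
        return sum(c[library] for c in self.counts.values())

    def count(self, seq: str, library: int) -> int:
        return self.counts.get(to_dna(seq), (0, 0))[library]

    def sequences(self) -> list[str]:
        return list(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, c[0], c[1]) for s, c in self.counts.items()],
            columns=["sequence", "count_leaf", "count_bud"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def size_filter(
    reads: Iterable[str], cfg: PreprocessConfig | None = None
) -> tuple[list[str], dict[str, int]]:
    """Keep reads with l_min <= length <= l_max; drop invalid characters.

    Returns (retained reads, stats) with stats counting input/retained/
    too_short/too_long/invalid.
    """
    cfg = cfg or PreprocessConfig()
    kept: list[str] = []
    stats = {"input": 0, "retained": 0, "too_short": 0, "too_long": 0, "invalid": 0}
    for read in reads:
        stats["input"] += 1
        seq = to_dna(read)
        if not set(seq) <= VALID_BASES:
            stats["invalid"] += 1
        elif len(seq) < cfg.l_min:
            stats["too_short"] += 1
        elif len(seq) > cfg.l_max:
            stats["too_long"] += 1
        else:
            stats["retained"] += 1
            kept.append(seq)
    return kept, stats


def collapse_and_count(
    leaf_reads: Iterable[str], bud_reads: Iterable[str]
) -> SmallReadSet:
    """Collapse size-filtered reads to unique sequences with exact counts."""
    leaf = Counter(to_dna(r) for r in leaf_reads)
    bud = Counter(to_dna(r) for r in bud_reads)
    counts = {
        seq: (leaf.get(seq, 0), bud.get(seq, 0)) for seq in sorted(leaf | bud)
    }
    return SmallReadSet(
        counts=counts, n_leaf=sum(leaf.values()), n_bud=sum(bud.values())
    )


def _matches_contaminant(seq: str, contaminants: dict[str, str], max_mm: int) -> bool:
    from .patmatch import _containment_distance

    rc = revcomp(seq)
    for cseq in contaminants.values():
        if max_mm == 0:
            if seq in cseq or rc in cseq:
                return True
        else:
            if (
                _containment_distance(seq, cseq) <= max_mm
                or _containment_distance(rc, cseq) <= max_mm
            ):
                return True
    return False


def remove_contaminants(
    rs: SmallReadSet,
    contaminants: dict[str, str],
    cfg: PreprocessConfig | None = None,
) -> tuple[SmallReadSet, dict[str, int]]:
    """Remove reads contained full-length in any contaminant sequence.

    Matching is either-strand substring containment with at most
    ``contaminant_max_mismatch`` substitutions.  An empty contaminant set
    is a no-op (removed counts zero).  Library totals n_leaf/n_bud are
    preserved: they denote reads surviving the size window.
    """
    cfg = cfg or PreprocessConfig()
    contaminants = {k: to_dna(v) for k, v in contaminants.items()}
    kept: dict[str, tuple[int, int]] = {}
    removed = {"leaf": 0, "bud": 0, "unique": 0}
    for seq, (cl, cb) in rs.counts.items():
        if contaminants and _matches_contaminant(
            seq, contaminants, cfg.contaminant_max_mismatch
        ):
            removed["leaf"] += cl
            removed["bud"] += cb
            removed["unique"] += 1
        else:
            kept[seq] = (cl, cb)
    return SmallReadSet(counts=kept, n_leaf=rs.n_leaf, n_bud=rs.n_bud), removed


@dataclass
class VariantGroup:
    representative: str
    members: list[str]
    count_leaf: int  # totals over all member variants
    count_bud: int


def group_length_variants(
    rs: SmallReadSet, sequences: Iterable[str] | None = None, max_offset: int = 2
) -> list[VariantGroup]:
    """Group sequences related by small 5'/3' end shifts.

    Two sequences belong to one group when one is a substring of the other
    with at most ``max_offset`` nt trimmed at each end (transitively
    closed).  The representative is the member with the highest total
    count across libraries; ties break to the longer variant, then the
    lexicographically smaller sequence.
    """
    seqs = sorted(sequences) if sequences is not None else sorted(rs.counts)
    index = {s: i for i, s in enumerate(seqs)}
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for s in seqs:
        i = index[s]
        for off5 in range(max_offset + 1):
            for off3 in range(max_offset + 1):
                if off5 == off3 == 0:
                    continue
                end = len(s) - off3
                if end - off5 < 1:
                    continue
                sub = s[off5:end]
                j = index.get(sub)
                if j is not None:
                    union(i, j)

    groups: dict[int, list[str]] = {}
    for s in seqs:
        groups.setdefault(find(index[s]), []).append(s)

    out = []
    for members in groups.values():
        members.sort(
            key=lambda s: (-(rs.count(s, 0) + rs.count(s, 1)), -len(s), s)
        )
        out.append(
            VariantGroup(
                representative=members[0],
                members=members,
                count_leaf=sum(rs.count(m, 0) for m in members),
                count_bud=sum(rs.count(m, 1) for m in members),
            )
        )
    out.sort(key=lambda g: g.representative)
    return out
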