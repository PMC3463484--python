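"""Approximate short-sequence search against genomes and reference sets.

Substitution-only matching (Hamming distance) on both strands, with a
multi-hit cap that flags likely repeat-derived reads.  This stands in for
the classical pattern-scan / short-read-mapping steps of small-RNA
pipelines: at read lengths of 18-24 nt a complete windowed scan is exact
and fast, and avoids heuristic seed-and-extend trade-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import revcomp, to_dna


@dataclass
class SearchConfig:
    """Substitution budgets for the three search contexts, plus the repeat cap.

    A read with more than ``max_hits`` genomic occurrences is flagged as
    repeat-derived and excluded from miRNA discovery (strict inequality:
    exactly ``max_hits`` hits is still retained).
    """

    max_subst_conserved: int = 2
    max_subst_genome_nonconserved: int = 0
    max_subst_mapping: int = 2
    max_hits: int = 10


@dataclass(frozen=True, order=True)
class GenomicHit:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    n_mismatches: int


def _scan_one_strand(query: str, text: str, k: int) -> list[tuple[int, int]]:
    """All (start, n_mismatches) of full-length windows with Hamming <= k."""
    m, n = len(query), len(text)
    if m > n:
        return []
    if k == 0:
        out = []
        pos = text.find(query)
        while pos != -1:
            out.append((pos, 0))
            pos = text.find(query, pos + 1)
        return out
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n_win = n - m + 1
    mm = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mm += t[j : j + n_win] != q[j]
    starts = np.flatnonzero(mm <= k)
    return [(int(s), int(mm[s])) for s in starts]


def find_all(
    query: str,
    text: str,
    k: int = 0,
    chrom: str = "text",
    both_strands: bool = True,
) -> list[GenomicHit]:
    """Every occurrence of ``query`` in ``text`` at Hamming distance <= k.

    Complete (no window missed), both strands unless disabled, ordered by
    (chrom, start, strand).  A minus-strand hit at [s, e) means the
    reverse complement of text[s:e] equals the query up to k substitutions.
    """
    q = to_dna(query)
    t = to_dna(text)
    m = len(q)
    hits = [
        GenomicHit(chrom, s, s + m, "+", d) for s, d in _scan_one_strand(q, t, k)
    ]
    if both_strands:
        hits += [
            GenomicHit(chrom, s, s + m, "-", d)
            for s, d in _scan_one_strand(revcomp(q), t, k)
        ]
    hits.sort()
    return hits


def map_reads(
    sequences: list[str],
    genome: dict[str, str],
    cfg: SearchConfig | None = None,
    k: int | None = None,
) -> tuple[dict[str, list[GenomicHit]], set[str]]:
    """Map unique read sequences to a genome; flag multi-hit (repeat) reads.

    Returns (hits per sequence, set of repeat-flagged sequences).  Reads
    with zero hits are retained in the dictionary with an empty list.
    Scanning stops early once a read exceeds ``max_hits`` occurrences
    (the hit list is then truncated; only the flag is meaningful).
    """
    cfg = cfg or SearchConfig()
    if k is None:
        k = cfg.max_subst_mapping
    cap = cfg.max_hits
    hits: dict[str, list[GenomicHit]] = {}
    repeat_flagged: set[str] = set()
    for seq in sequences:
        acc: list[GenomicHit] = []
        for chrom, text in genome.items():
            acc.extend(find_all(seq, text, k=k, chrom=chrom))
            if len(acc) > cap:
                break
        hits[seq] = acc
        if len(acc) > cap:
            repeat_flagged.add(seq)
    return hits, repeat_flagged


def _containment_distance(short: str, long_: str) -> int:
    """Best Hamming distance of ``short`` over all windows of ``long_``."""
    best = len(short) + 1
    for s, d in _scan_one_strand(short, long_, len(short)):
        best = min(best, d)
    return best


def match_distance(read: str, reference: str, length_slack: int = 2) -> int | None:
    """Substitution distance between a read and a reference mature sequence.

    Equal lengths compare position-wise; otherwise the shorter sequence is
    slid along the longer (containment), provided the length difference is
    at most ``length_slack``.  Returns None when lengths are incompatible.
    """
    r, f = to_dna(read), to_dna(reference)
    if len(r) == len(f):
        return sum(a != b for a, b in zip(r, f))
    if abs(len(r) - len(f)) > length_slack:
        return None
    short, long_ = (r, f) if len(r) < len(f) else (f, r)
    return _containment_distance(short, long_)


def family_of(reference_id: str) -> str:
    """Family label of a reference id: the part before the first underscore."""
    return reference_id.split("_")[0]


def match_known_mirnas(
    sequences: list[str],
    reference: dict[str, str],
    cfg: SearchConfig | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Partition reads into known-miRNA homologs and a remainder.

    A read is a conserved candidate when some reference mature sequence
    matches at <= ``max_subst_conserved`` substitutions (full length, with
    +/-2 nt length slack via containment).  It is labelled with the family
    of the minimum-distance reference; ties break to the lexicographically
    first family name.  Returns ({sequence: family}, remainder list);
    the two partitions are disjoint and cover the input.
    """
    cfg = cfg or SearchConfig()
    conserved: dict[str, str] = {}
    remainder: list[str] = []
    fams = sorted(reference.items(), key=lambda kv: (family_of(kv[0]), kv[0]))
    for seq in sequences:
        best: tuple[int, str] | None = None
        for ref_id, ref_seq in fams:
            d = match_distance(seq, ref_seq)
            if d is not None and d <= cfg.max_subst_conserved:
                fam = family_of(ref_id)
                if best is None or (d, fam) < best:
                    best = (d, fam)
        if best is None:
            remainder.append(seq)
        else:
            conserved[seq] = best[1]
    return conserved, remainder
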