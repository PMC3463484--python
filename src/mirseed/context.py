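"""Genomic distribution and QTL co-localization of annotated loci.

A likelihood-ratio goodness-of-fit (G) test asks whether loci are spread
across chromosomes as expected (proportional to chromosome length by
default, or uniformly), and interval intersection reports which loci and
target genes fall inside user-supplied QTL intervals (BED, 0-based
half-open).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


@dataclass(frozen=True)
class QTLInterval:
    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty QTL interval {self.label}")


def read_bed(path: str | Path) -> list[QTLInterval]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else f"interval_{i}"
            out.append(QTLInterval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def write_bed(path: str | Path, intervals: list[QTLInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def g_test(
    observed,
    expected=None,
    chrom_lengths: dict[str, int] | None = None,
    model: str = "length",
) -> tuple[float, float]:
    """Goodness-of-fit G test: G = 2 sum O_i ln(O_i / E_i), chi² with k-1 df.

    ``observed`` is a mapping chrom -> count or an array.  Expected counts
    come from ``expected`` if given, otherwise from the model:
    'length' (proportional to ``chrom_lengths``) or 'uniform'.  Cells
    with O_i = 0 contribute 0 (the 0*ln(0) convention).
    """
    if isinstance(observed, dict):
        keys = sorted(observed)
        obs = np.array([observed[k] for k in keys], dtype=float)
        if expected is None:
            if model == "length":
                if chrom_lengths is None:
                    raise ValueError("length model needs chrom_lengths")
                w = np.array([chrom_lengths[k] for k in keys], dtype=float)
            elif model == "uniform":
                w = np.ones(len(keys))
            else:
                raise ValueError(f"unknown expected model {model!r}")
            expected = obs.sum() * w / w.sum()
    else:
        obs = np.asarray(observed, dtype=float)
        if expected is None:
            if model != "uniform":
                raise ValueError("array input without expected requires model='uniform'")
            expected = np.full(len(obs), obs.sum() / len(obs))
    exp = np.asarray(expected, dtype=float)
    if len(obs) < 2:
        raise ValueError("G test needs at least two categories")
    total = obs.sum()
    if total == 0:
        raise ValueError("all observed counts are zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    p = float(stats.chi2.sf(g, df=len(obs) - 1))
    return float(g), p


def colocalize(
    loci: pd.DataFrame,
    qtls: list[QTLInterval],
    chrom_namespace: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Intersect locus intervals with QTL intervals (>= 1 bp overlap).

    ``loci`` needs columns id, chrom, start, end and optionally family.
    When ``chrom_namespace`` is given (e.g. the genome's chromosome ids),
    loci on chromosomes outside it are flagged and excluded.  Returns
    (overlap table with one row per locus-QTL intersection, per-family
    tallies over co-localized loci, flagged ids).  Half-open semantics:
    a locus starting exactly at a QTL end does not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for q in qtls:
        trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end, q.label)

    rows = []
    flagged: list[str] = []
    for rec in loci.itertuples(index=False):
        if chrom_namespace is not None and rec.chrom not in chrom_namespace:
            flagged.append(rec.id)
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(rec.start, rec.end)):
            rows.append(
                {
                    "id": rec.id,
                    "family": getattr(rec, "family", ""),
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.end,
                    "qtl": iv.data,
                    "qtl_start": iv.begin,
                    "qtl_end": iv.end,
                }
            )
    overlap = pd.DataFrame(
        rows,
        columns=["id", "family", "chrom", "start", "end", "qtl", "qtl_start", "qtl_end"],
    )
    if len(overlap):
        fam = (
            overlap.drop_duplicates("id")
            .groupby("family")
            .size()
            .rename("n_loci")
            .reset_index()
        )
    else:
        fam = pd.DataFrame(columns=["family", "n_loci"])
    return overlap, fam, flagged


def chromosome_counts(loci: pd.DataFrame, chroms: list[str]) -> dict[str, int]:
    """Observed locus counts per chromosome (zeros included)."""
    counts = {c: 0 for c in chroms}
    for c in loci["chrom"]:
        if c in counts:
            counts[c] += 1
    return counts
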