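"""miRNA target prediction by complementarity penalty scoring.

Each miRNA (5'->3') is aligned antiparallel against coding sequences and
a penalty is accumulated per position: Watson-Crick pair 0, G:U wobble
0.5, mismatch 1, gap 2, all doubled when the miRNA position falls in the
5' region (positions 2-13).  Sites scoring below the acceptance threshold
(default: strictly less than 4) are reported; per (miRNA, CDS) pair the
minimal-score site is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import to_dna, to_rna

GAP = "-"


@dataclass
class ScoringScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    region: tuple[int, int] = (2, 13)  # 1-based inclusive miRNA positions
    region_factor: float = 2.0
    max_gaps: int = 1
    max_score: float = 4.0  # acceptance is strict "<"

    def factor(self, pos: int) -> float:
        """Penalty multiplier for a 1-based miRNA position."""
        lo, hi = self.region
        return self.region_factor if lo <= pos <= hi else 1.0


def _pair_class(mirna_base: str, target_base: str) -> str:
    """'wc', 'wobble' or 'mismatch' for a miRNA base vs an mRNA base.

    The target base is given in its 3'->5' reading at the aligned
    position; T is treated as U (CDS files are DNA, the target is mRNA).
    """
    a = to_rna(mirna_base)
    b = to_rna(target_base)
    if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return "wc"
    if (a, b) in {("G", "U"), ("U", "G")}:
        return "wobble"
    return "mismatch"


def score_alignment(
    mirna_aln: str, target_aln: str, scheme: ScoringScheme | None = None
) -> float:
    """Penalty score of an explicit alignment.

    ``mirna_aln`` is the miRNA 5'->3' and ``target_aln`` the target site
    3'->5', both with '-' for gaps, equal length.  Insertions (gap in the
    miRNA) take the multiplier of the next miRNA position.
    """
    scheme = scheme or ScoringScheme()
    if len(mirna_aln) != len(target_aln):
        raise ValueError("aligned strings must have equal length")
    m = sum(1 for c in mirna_aln if c != GAP)
    score = 0.0
    pos = 0  # miRNA bases consumed
    for a, b in zip(mirna_aln, target_aln):
        if a == GAP and b == GAP:
            raise ValueError("column with gaps on both strands")
        if a == GAP:
            score += scheme.gap * scheme.factor(min(pos + 1, m))
        elif b == GAP:
            pos += 1
            score += scheme.gap * scheme.factor(pos)
        else:
            pos += 1
            cls = _pair_class(a, b)
            if cls == "wobble":
                score += scheme.wobble * scheme.factor(pos)
            elif cls == "mismatch":
                score += scheme.mismatch * scheme.factor(pos)
    return score


@dataclass
class TargetHit:
    mirna_id: str
    cds_id: str
    score: float
    site_start: int  # on the CDS, 0-based half-open, 5'->3'
    site_end: int
    mirna_aln: str
    target_aln: str  # 3'->5'


def _substitution_costs(mirna: str, rev_cds: str, scheme: ScoringScheme) -> np.ndarray:
    """cost[i, j]: aligning miRNA base i+1 with rev_cds base j (0-based)."""
    m, n = len(mirna), len(rev_cds)
    cost = np.zeros((m, n))
    for i in range(m):
        f = scheme.factor(i + 1)
        row = np.empty(n)
        for j in range(n):
            cls = _pair_class(mirna[i], rev_cds[j])
            row[j] = 0.0 if cls == "wc" else (scheme.wobble if cls == "wobble" else scheme.mismatch)
        cost[i] = row * f
    return cost


def _align_one(
    mirna: str, cds: str, scheme: ScoringScheme
) -> tuple[float, int, int, str, str] | None:
    """Minimal-penalty semi-global alignment of a miRNA against one CDS.

    The miRNA is aligned in full; the site floats freely within the CDS.
    At most ``scheme.max_gaps`` gaps (currently 0 or 1 supported by the
    layered DP).  Returns (score, site_start, site_end, mirna_aln,
    target_aln) or None for an empty CDS.
    """
    m, n = len(mirna), len(cds)
    if n == 0 or m == 0 or m > n + scheme.max_gaps:
        return None
    rev = cds[::-1]  # align miRNA 5'->3' with the CDS read 3'->5'
    sub = _substitution_costs(mirna, rev, scheme)
    INF = np.inf
    layers = scheme.max_gaps + 1
    # dp[g][i][j]: min cost, i miRNA bases and j rev-CDS bases consumed, g gaps
    dp = np.full((layers, m + 1, n + 1), INF)
    dp[0, 0, :] = 0.0  # free start anywhere in the target
    for i in range(1, m + 1):
        diag = dp[0, i - 1, :-1] + sub[i - 1]
        dp[0, i, 1:] = diag
        if layers > 1:
            del_cost = scheme.gap * scheme.factor(i)
            ins_cost = scheme.gap * scheme.factor(min(i + 1, m))
            d1 = dp[1, i - 1, :-1] + sub[i - 1]
            dele = dp[0, i - 1, :] + del_cost  # miRNA base vs gap
            dp[1, i, :] = np.minimum(dp[1, i, :], dele)
            dp[1, i, 1:] = np.minimum(np.minimum(dp[1, i, 1:], d1), dele[1:])
            ins = dp[0, i, :-1] + ins_cost  # gap in miRNA vs target base
            dp[1, i, 1:] = np.minimum(dp[1, i, 1:], ins)
    # insertion after the last miRNA base would extend the site for free
    # penalty; allowed by the recurrence above only between consumed bases.
    best_layer, best_j = min(
        ((g, int(np.argmin(dp[g, m, :]))) for g in range(layers)),
        key=lambda gj: dp[gj[0], m, gj[1]],
    )
    score = float(dp[best_layer, m, best_j])
    if not np.isfinite(score):
        return None
    # traceback
    g, i, j = best_layer, m, best_j
    a_out: list[str] = []
    b_out: list[str] = []
    while i > 0:
        if j > 0 and np.isclose(dp[g, i, j], dp[g, i - 1, j - 1] + sub[i - 1, j - 1]):
            a_out.append(mirna[i - 1])
            b_out.append(rev[j - 1])
            i, j = i - 1, j - 1
        elif g > 0 and np.isclose(
            dp[g, i, j], dp[g - 1, i - 1, j] + scheme.gap * scheme.factor(i)
        ):
            a_out.append(mirna[i - 1])
            b_out.append(GAP)
            g, i = g - 1, i - 1
        elif (
            g > 0
            and j > 0
            and np.isclose(
                dp[g, i, j],
                dp[g - 1, i, j - 1] + scheme.gap * scheme.factor(min(i + 1, m)),
            )
        ):
            a_out.append(GAP)
            b_out.append(rev[j - 1])
            g, j = g - 1, j - 1
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    j_start = j
    site_start, site_end = n - best_j, n - j_start
    return score, site_start, site_end, "".join(reversed(a_out)), "".join(reversed(b_out))


def find_targets(
    mirnas: dict[str, str],
    cds_set: dict[str, str],
    scheme: ScoringScheme | None = None,
) -> list[TargetHit]:
    """All (miRNA, CDS) hits below the acceptance threshold.

    Per pair the minimal-score site is reported; output sorted by
    (miRNA id, score ascending, CDS id).
    """
    scheme = scheme or ScoringScheme()
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        mseq = to_dna(mirnas[mid])
        for cid in sorted(cds_set):
            res = _align_one(mseq, to_dna(cds_set[cid]), scheme)
            if res is None:
                continue
            score, s, e, a_aln, b_aln = res
            if score < scheme.max_score:
                hits.append(TargetHit(mid, cid, score, s, e, a_aln, b_aln))
    hits.sort(key=lambda h: (h.mirna_id, h.score, h.cds_id))
    return hits


def best_hits(hits: list[TargetHit]) -> list[TargetHit]:
    """The subset achieving each miRNA's minimal score."""
    best: dict[str, float] = {}
    for h in hits:
        best[h.mirna_id] = min(best.get(h.mirna_id, np.inf), h.score)
    return [h for h in hits if np.isclose(h.score, best[h.mirna_id])]


def hits_to_frame(hits: list[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.mirna_id, h.score, h.cds_id, h.site_start, h.site_end, h.mirna_aln, h.target_aln)
            for h in hits
        ],
        columns=["mirna", "score", "cds", "site_start", "site_end", "mirna_aln", "target_aln"],
    )


def target_coverage_percent(n_with_target: int, n_total: int) -> float:
    """Share of miRNAs with at least one predicted target, in percent
    rounded to one decimal (the convention used for reported tables)."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_with_target / n_total, 1)
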