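"""Precursor extraction, folding, star prediction and hairpin criteria.

Candidate mature sequences anchored on the genome are extended by a flank
on each side, folded, and evaluated against stem-loop criteria in the
MirCheck/community-annotation tradition: the mature must sit on one arm
of a fold-back, mostly paired, with limited asymmetric bulging and few
duplex mismatches.  The star (partner strand) is predicted from the pair
table via the 2-nt 3' overhang geometry of Dicer products, and star reads
are looked up in the collapsed read set as the biogenesis evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import DEFAULT_MIN_LOOP, FoldResult, fold
from .patmatch import GenomicHit
from .preprocess import SmallReadSet
from .seqs import revcomp, to_dna


@dataclass
class HairpinConfig:
    flank: int = 150  # nt of genomic context on each side of the mature
    min_loop: int = DEFAULT_MIN_LOOP
    overhang: int = 2  # nt of 3' overhang on each duplex end
    min_mature_paired_frac: float = 0.6
    max_unpaired_mature: int = 4
    max_asymmetric_bulge: int = 2
    max_duplex_mismatch: int = 4
    engine: str = "builtin"  # or "vienna" for thermodynamic MFE folding


@dataclass
class CriteriaReport:
    """Per-criterion verdicts with the measured values retained for review."""

    unpaired_mature: int
    asymmetric_bulge: int
    duplex_mismatches: int
    loop_overlap: bool
    star_predicted: bool
    passed: bool
    reason: str = ""


@dataclass
class HairpinCandidate:
    chrom: str
    precursor_start: int  # genomic, 0-based half-open, on + coordinates
    precursor_end: int
    strand: str
    precursor: str  # 5'->3' on the candidate strand (DNA alphabet)
    mature_offset: int  # within precursor
    mature_length: int
    clipped: bool = False
    fold_result: FoldResult | None = None
    star_offset: int | None = None
    star_length: int | None = None
    report: CriteriaReport | None = None
    star_observed: tuple[bool, bool] = (False, False)  # (leaf, bud)

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature_offset : self.mature_offset + self.mature_length]

    @property
    def star_seq(self) -> str | None:
        if self.star_offset is None:
            return None
        return self.precursor[self.star_offset : self.star_offset + self.star_length]


def extract_precursor(
    hit: GenomicHit, genome: dict[str, str], cfg: HairpinConfig | None = None
) -> HairpinCandidate:
    """Slice the mature hit plus ``flank`` nt of genomic context each side.

    Minus-strand hits are reverse complemented so the precursor always
    reads 5'->3' with the mature on the sense strand.  Hits within a flank
    of a contig edge are clipped and flagged.
    """
    cfg = cfg or HairpinConfig()
    text = genome[hit.chrom]
    lo = max(0, hit.start - cfg.flank)
    hi = min(len(text), hit.end + cfg.flank)
    clipped = lo > hit.start - cfg.flank or hi < hit.end + cfg.flank
    window = text[lo:hi]
    if hit.strand == "+":
        mature_offset = hit.start - lo
    else:
        window = revcomp(window)
        mature_offset = hi - hit.end
    return HairpinCandidate(
        chrom=hit.chrom,
        precursor_start=lo,
        precursor_end=hi,
        strand=hit.strand,
        precursor=to_dna(window),
        mature_offset=mature_offset,
        mature_length=hit.end - hit.start,
        clipped=clipped,
    )


def best_duplex_chain(
    pt: list[int], a: int, b: int
) -> list[tuple[int, int]] | None:
    """Best antiparallel mature/star pairing chain of a folded mature [a, b).

    The fold may pair a few mature bases away from the true partner arm
    (a base-pair maximizer is free to do so when co-optimal); criteria
    should count those as imperfections, not reject the hairpin.  This
    selects, among the mature base pairs whose partners lie on the
    majority side of the mature, the strictly antiparallel subchain
    minimizing dropped bases plus bulge penalties — the best duplex
    interpretation of the structure.  Returns [(mature_pos, partner), ...]
    or None when the mature mostly pairs with itself (it spans the loop)
    or has no partners at all.
    """
    paired = [(i, pt[i]) for i in range(a, b) if pt[i] >= 0]
    if not paired:
        return None
    self_pairs = sum(1 for _, p in paired if a <= p < b)
    if self_pairs > 0.2 * len(paired):
        return None  # mature folds back on itself: spans the terminal loop
    left = [(i, p) for i, p in paired if p < a]
    right = [(i, p) for i, p in paired if p >= b]
    cand = left if len(left) > len(right) else right
    if not cand:
        return None
    # DP over candidates in mature order: chain with strictly decreasing
    # partners, minimizing unpaired mature bases + max(bulge) per gap.
    n = len(cand)
    INF = float("inf")
    cost = [INF] * n
    prev: list[int | None] = [None] * n
    for j, (ij, pj) in enumerate(cand):
        cost[j] = float(ij - a)  # leading mature bases left unpaired
        for k in range(j):
            ik, pk = cand[k]
            if pk <= pj:
                continue
            dm = ij - ik - 1
            ds = pk - pj - 1
            c = cost[k] + dm + max(dm, ds)
            if c < cost[j]:
                cost[j], prev[j] = c, k
    end = min(range(n), key=lambda j: cost[j] + (b - 1 - cand[j][0]))
    chain = []
    j: int | None = end
    while j is not None:
        chain.append(cand[j])
        j = prev[j]
    chain.reverse()
    return chain


def _extrapolate(chain: list[tuple[int, int]], x: int) -> int:
    """Partner of mature position x extrapolated from the nearest chain pair
    (locally perfect duplex: partner decreases as the mature index grows)."""
    i, p = min(chain, key=lambda ip: (abs(ip[0] - x), ip[0]))
    return p - (x - i)


def predict_star(
    fold_result: FoldResult,
    mature_offset: int,
    mature_length: int,
    cfg: HairpinConfig | None = None,
) -> tuple[int, int] | None:
    """Predicted star interval (offset, length) from the duplex geometry.

    The star occupies the positions pairing with the mature on the
    opposite arm, shifted so that both duplex 3' ends carry an
    ``overhang``-nt overhang.  Returns None when the mature is too poorly
    paired or spans the terminal loop.
    """
    cfg = cfg or HairpinConfig()
    pt = fold_result.pair_table
    a, b = mature_offset, mature_offset + mature_length
    chain = best_duplex_chain(pt, a, b)
    if chain is None or len(chain) < cfg.min_mature_paired_frac * mature_length:
        return None
    o = cfg.overhang
    e1 = _extrapolate(chain, b - 1 - o)
    e2 = _extrapolate(chain, a) + o
    lo, hi = min(e1, e2), max(e1, e2) + 1
    lo = max(0, lo)
    hi = min(len(pt), hi)
    if hi <= lo or (lo < b and hi > a):
        return None  # degenerate or overlapping the mature itself
    return lo, hi - lo


def evaluate_criteria(
    fold_result: FoldResult,
    mature_offset: int,
    mature_length: int,
    cfg: HairpinConfig | None = None,
) -> tuple[CriteriaReport, tuple[int, int] | None]:
    """Hairpin criteria on a folded precursor with a placed mature.

    Measures, against the best duplex chain (see
    :func:`best_duplex_chain`): (a) mature bases not in the duplex,
    (b) asymmetric bulge nucleotides within the duplex, (c) duplex
    mismatches (symmetric internal-loop positions), and (d) whether the
    mature spans the terminal loop; passes when all are within the
    configured thresholds and a star placement exists.
    """
    cfg = cfg or HairpinConfig()
    pt = fold_result.pair_table
    a, b = mature_offset, mature_offset + mature_length
    chain = best_duplex_chain(pt, a, b)
    loop_overlap = chain is None

    if chain is None:
        unpaired = sum(1 for i in range(a, b) if pt[i] < 0)
        asym = 0
        mism = 0
    else:
        unpaired = mature_length - len(chain)
        asym = 0
        mism = 0
        for (i1, p1), (i2, p2) in zip(chain, chain[1:]):
            d_mature = i2 - i1 - 1
            d_star = p1 - p2 - 1
            mism += min(d_mature, d_star)
            asym += abs(d_mature - d_star)

    star = None
    if not loop_overlap:
        star = predict_star(fold_result, mature_offset, mature_length, cfg)

    checks = {
        "unpaired_mature": unpaired <= cfg.max_unpaired_mature,
        "asymmetric_bulge": asym <= cfg.max_asymmetric_bulge,
        "duplex_mismatches": mism <= cfg.max_duplex_mismatch,
        "loop_overlap": not loop_overlap,
        "star_predicted": star is not None,
    }
    failed = [name for name, ok in checks.items() if not ok]
    report = CriteriaReport(
        unpaired_mature=unpaired,
        asymmetric_bulge=asym,
        duplex_mismatches=mism,
        loop_overlap=loop_overlap,
        star_predicted=star is not None,
        passed=not failed,
        reason=",".join(failed),
    )
    return report, star


def evaluate_candidate(
    cand: HairpinCandidate, cfg: HairpinConfig | None = None
) -> HairpinCandidate:
    """Fold a candidate precursor and fill in star placement and criteria."""
    cfg = cfg or HairpinConfig()
    if len(cand.precursor) < 2 * cand.mature_length + cfg.min_loop:
        cand.report = CriteriaReport(
            unpaired_mature=cand.mature_length,
            asymmetric_bulge=0,
            duplex_mismatches=0,
            loop_overlap=True,
            star_predicted=False,
            passed=False,
            reason="fail-fold: precursor too short",
        )
        return cand
    cand.fold_result = fold(cand.precursor, min_loop=cfg.min_loop, engine=cfg.engine)
    report, star = evaluate_criteria(
        cand.fold_result, cand.mature_offset, cand.mature_length, cfg
    )
    cand.report = report
    if star is not None:
        cand.star_offset, cand.star_length = star
    return cand


def star_sequence_variants(
    precursor: str, star_offset: int, star_length: int, shift: int = 1
) -> set[str]:
    """Star sequence plus all +/-``shift`` single-end variants."""
    out = set()
    n = len(precursor)
    for d5 in range(-shift, shift + 1):
        for d3 in range(-shift, shift + 1):
            lo = star_offset + d5
            hi = star_offset + star_length + d3
            if 0 <= lo < hi <= n:
                out.add(precursor[lo:hi])
    return out


def detect_star_reads(
    cand: HairpinCandidate, rs: SmallReadSet, shift: int = 1
) -> tuple[bool, bool]:
    """Whether a sequenced read matches the predicted star, per library.

    True for a library iff some read equals the predicted star sequence
    exactly or within a +/-1-nt end shift, with at least one count there.
    """
    if cand.star_offset is None:
        cand.star_observed = (False, False)
        return cand.star_observed
    variants = star_sequence_variants(
        cand.precursor, cand.star_offset, cand.star_length, shift
    )
    leaf = any(rs.count(v, 0) > 0 for v in variants)
    bud = any(rs.count(v, 1) > 0 for v in variants)
    cand.star_observed = (leaf, bud)
    return cand.star_observed
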