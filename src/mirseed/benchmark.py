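"""Plant-and-recover metrics: compare pipeline output to simulation truth.

Matching is by mature sequence: the annotation representative is the
dominant length variant, which for a planted locus is the planted mature
itself.  A genomic-interval match is deliberately not required because a
perfect fold-back contains the mature sequence twice (once as the star
arm's reverse complement), and either anchor is a correct call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import MiRNAAnnotation
from .simulate import LocusTruth, SimResult


@dataclass
class RecoveryReport:
    n_eligible: int
    n_recovered: int
    repeat_annotated: int
    missed: list[str]

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 1.0


def eligible_loci(sim: SimResult, r_min: int = 2) -> list[LocusTruth]:
    """Planted loci the pipeline is expected to recover: non-repeat, with
    sequenced star reads, and enough mature reads to pass the count screen."""
    out = []
    for t in sim.truth:
        if t.cls == "repeat":
            continue
        if t.star_count_leaf + t.star_count_bud == 0:
            continue
        if max(t.count_leaf, t.count_bud) < r_min:
            continue
        out.append(t)
    return out


def recovery(
    sim: SimResult, annotations: list[MiRNAAnnotation], r_min: int = 2
) -> RecoveryReport:
    """Fraction of eligible planted loci present in the annotation set,
    plus the number of annotations matching a planted repeat sequence."""
    annotated_seqs = {a.mature_seq for a in annotations}
    eligible = eligible_loci(sim, r_min)
    missed = [t.locus_id for t in eligible if t.mature_seq not in annotated_seqs]
    repeat_seqs = {t.mature_seq for t in sim.truth if t.cls == "repeat"}
    n_repeat = sum(1 for a in annotations if a.mature_seq in repeat_seqs)
    return RecoveryReport(
        n_eligible=len(eligible),
        n_recovered=len(eligible) - len(missed),
        repeat_annotated=n_repeat,
        missed=missed,
    )


def de_recall(
    sim: SimResult,
    annotations: list[MiRNAAnnotation],
    up_in_bud_ids: list[str],
    min_expected_count: int = 200,
    fold: float = 8.0,
) -> tuple[int, int]:
    """(recalled, total) planted bud-induced loci among the DE calls.

    Counts planted loci with the given fold change whose realized bud
    count reaches ``min_expected_count`` and asks whether the matching
    annotation was called up-in-bud.  Only annotatable loci enter the
    denominator: a novel locus whose star was never sequenced is
    excluded by the biogenesis rule before any test runs, so it cannot
    measure the caller's power.
    """
    seq_to_id = {a.mature_seq: a.id for a in annotations}
    called = set(up_in_bud_ids)
    total = 0
    recalled = 0
    for t in sim.truth:
        if t.cls == "repeat" or t.fold_change != fold:
            continue
        if t.count_bud < min_expected_count:
            continue
        if t.cls == "novel" and t.star_count_leaf + t.star_count_bud == 0:
            continue
        total += 1
        if seq_to_id.get(t.mature_seq) in called:
            recalled += 1
    return recalled, total
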