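"""Final miRNA annotation under the community criteria for plant miRNAs.

Two branches share the hairpin evidence but differ in stringency:

* conserved candidates (homologs of known families) are accepted in
  evidence tiers — sequenced star (biogenesis), expression in both
  libraries or strong accumulation in one (expression-ancillary), an
  already-accepted family member (family-ancillary), or an external
  conservation flag (conservation-ancillary).  Families suspected to be
  repeat-derived can be restricted to the biogenesis tier.
* non-conserved candidates require the full biogenesis evidence: hairpin
  pass, a sequenced star in at least one library, and a minimum read
  count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .hairpin import HairpinCandidate

TIER_BIOGENESIS = "biogenesis"
TIER_EXPRESSION = "expression-ancillary"
TIER_FAMILY = "family-ancillary"
TIER_CONSERVATION = "conservation-ancillary"


@dataclass
class AnnotateConfig:
    strong_accum: int = 10  # reads in one library counting as strong accumulation
    r_min: int = 2  # minimum reads (in at least one library) for non-conserved
    repeat_flagged_families: frozenset[str] = frozenset()


@dataclass
class Candidate:
    """Evidence bundle for one unique (representative) sequence."""

    id: str
    sequence: str
    hairpin: HairpinCandidate
    count_leaf: int  # totals over length variants
    count_bud: int
    family: str = ""
    conservation_flag: bool = False
    dominant_count_leaf: int | None = None  # dominant length variant only
    dominant_count_bud: int | None = None


@dataclass
class MiRNAAnnotation:
    id: str
    cls: str  # "conserved" | "non-conserved"
    family: str
    mature_seq: str
    chrom: str
    start: int  # genomic interval of the mature, 0-based half-open
    end: int
    strand: str
    star_seq: str | None
    tier: str
    count_leaf: int
    count_bud: int
    tissue: str  # "both" | "leaf-specific" | "bud-specific" | "neither"

    @staticmethod
    def _tissue(count_leaf: int, count_bud: int) -> str:
        if count_leaf > 0 and count_bud > 0:
            return "both"
        if count_leaf > 0:
            return "leaf-specific"
        if count_bud > 0:
            return "bud-specific"
        return "neither"


def _mature_interval(h: HairpinCandidate) -> tuple[int, int]:
    if h.strand == "+":
        s = h.precursor_start + h.mature_offset
    else:
        s = h.precursor_end - h.mature_offset - h.mature_length
    return s, s + h.mature_length


def _build(cand: Candidate, cls: str, tier: str) -> MiRNAAnnotation:
    s, e = _mature_interval(cand.hairpin)
    return MiRNAAnnotation(
        id=cand.id,
        cls=cls,
        family=cand.family,
        mature_seq=cand.sequence,
        chrom=cand.hairpin.chrom,
        start=s,
        end=e,
        strand=cand.hairpin.strand,
        star_seq=cand.hairpin.star_seq,
        tier=tier,
        count_leaf=cand.count_leaf,
        count_bud=cand.count_bud,
        tissue=MiRNAAnnotation._tissue(cand.count_leaf, cand.count_bud),
    )


def annotate_conserved(
    candidates: list[Candidate], cfg: AnnotateConfig | None = None
) -> list[MiRNAAnnotation]:
    """Tiered acceptance of conserved candidates that passed the hairpin.

    Tier order: (1) star sequenced in either library; (2) expression in
    both libraries or >= ``strong_accum`` reads in one; (3) another
    accepted member of the same family; (4) external conservation flag.
    Members of repeat-flagged families are only accepted at tier (1).
    Family-ancillary acceptance iterates to a fixed point so that order
    of input does not matter.
    """
    cfg = cfg or AnnotateConfig()
    passed = [c for c in candidates if c.hairpin.report and c.hairpin.report.passed]
    accepted: dict[str, MiRNAAnnotation] = {}
    deferred: list[Candidate] = []

    for c in sorted(passed, key=lambda c: c.id):
        star = any(c.hairpin.star_observed)
        if star:
            accepted[c.id] = _build(c, "conserved", TIER_BIOGENESIS)
            continue
        if c.family in cfg.repeat_flagged_families:
            continue  # suspected repeat family: biogenesis evidence required
        expressed_both = c.count_leaf > 0 and c.count_bud > 0
        strong = max(c.count_leaf, c.count_bud) >= cfg.strong_accum
        if expressed_both or strong:
            accepted[c.id] = _build(c, "conserved", TIER_EXPRESSION)
        else:
            deferred.append(c)

    changed = True
    while changed:
        changed = False
        families = {ann.family for ann in accepted.values()}
        for c in list(deferred):
            if c.family in families:
                accepted[c.id] = _build(c, "conserved", TIER_FAMILY)
                deferred.remove(c)
                changed = True

    for c in deferred:
        if c.conservation_flag:
            accepted[c.id] = _build(c, "conserved", TIER_CONSERVATION)

    return sorted(accepted.values(), key=lambda a: a.id)


def annotate_nonconserved(
    candidates: list[Candidate], cfg: AnnotateConfig | None = None
) -> list[MiRNAAnnotation]:
    """Accept iff hairpin pass, star sequenced in >= 1 library, and total
    count >= ``r_min`` in at least one library."""
    cfg = cfg or AnnotateConfig()
    out = []
    for c in sorted(candidates, key=lambda c: c.id):
        if not (c.hairpin.report and c.hairpin.report.passed):
            continue
        if not any(c.hairpin.star_observed):
            continue
        if max(c.count_leaf, c.count_bud) < cfg.r_min:
            continue
        out.append(_build(c, "non-conserved", TIER_BIOGENESIS))
    return out


def family_stats(annotations: list[MiRNAAnnotation]) -> dict:
    """Family sizes, tissue-specificity tallies and per-class totals."""
    fam: dict[str, int] = {}
    tissue = {"both": 0, "leaf-specific": 0, "bud-specific": 0, "neither": 0}
    cls: dict[str, int] = {}
    for a in annotations:
        key = a.family or a.id
        fam[key] = fam.get(key, 0) + 1
        tissue[a.tissue] += 1
        cls[a.cls] = cls.get(a.cls, 0) + 1
    return {"family_sizes": fam, "tissue": tissue, "classes": cls, "total": len(annotations)}


def annotations_to_frame(annotations: list[MiRNAAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": a.id,
                "class": a.cls,
                "family": a.family,
                "len": len(a.mature_seq),
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "star_observed": a.tier == TIER_BIOGENESIS,
                "tier": a.tier,
                "mature_seq": a.mature_seq,
                "star_seq": a.star_seq or "",
                "count_leaf": a.count_leaf,
                "count_bud": a.count_bud,
                "tissue": a.tissue,
            }
            for a in annotations
        ]
    )
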