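"""End-to-end discovery pipeline.

Stages: read cleaning -> genome mapping and multi-hit repeat filter ->
split into known-family homologs and remainder -> hairpin evaluation and
annotation (conserved and non-conserved branches) -> differential
expression -> target prediction -> chromosome distribution and QTL
co-localization.  Each stage logs per-library read accounting so the
cascade table is always derivable from a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    AnnotateConfig,
    Candidate,
    MiRNAAnnotation,
    annotate_conserved,
    annotate_nonconserved,
    annotations_to_frame,
    family_stats,
)
from .context import QTLInterval, chromosome_counts, colocalize, g_test, read_bed
from .diffexpr import call_de, fisher_test, lr_test, ma_test
from .hairpin import (
    HairpinCandidate,
    HairpinConfig,
    detect_star_reads,
    evaluate_candidate,
    extract_precursor,
)
from .patmatch import GenomicHit, SearchConfig, map_reads, match_known_mirnas
from .preprocess import (
    PreprocessConfig,
    SmallReadSet,
    VariantGroup,
    collapse_and_count,
    group_length_variants,
    remove_contaminants,
    size_filter,
)
from .seqs import iter_reads, read_fasta
from .targets import ScoringScheme, find_targets, hits_to_frame, target_coverage_percent


@dataclass
class PipelineConfig:
    genome: str
    leaf: str
    bud: str
    contaminants: str
    reference: str  # known mature miRNAs (FASTA)
    cds: str | None = None
    qtl: str | None = None
    outdir: str = "mirseed_out"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    hairpin: HairpinConfig = field(default_factory=HairpinConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    de_method: str = "ma"  # ma | fisher | lrt
    de_alpha: float = 0.05
    de_counting: str = "total"  # total (over variants) | dominant
    max_hits_evaluated: int = 3  # genomic loci folded per candidate sequence

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _choose_candidate(
    seq: str,
    hits: list[GenomicHit],
    genome: dict[str, str],
    rs: SmallReadSet,
    cfg: PipelineConfig,
) -> HairpinCandidate | None:
    """Evaluate up to ``max_hits_evaluated`` genomic loci for a sequence and
    keep the best: criteria pass with observed star > pass > first."""
    best: HairpinCandidate | None = None
    best_rank = -1
    for hit in hits[: cfg.max_hits_evaluated]:
        cand = evaluate_candidate(extract_precursor(hit, genome, cfg.hairpin), cfg.hairpin)
        if cand.report and cand.report.passed:
            detect_star_reads(cand, rs)
            rank = 2 if any(cand.star_observed) else 1
        else:
            rank = 0
        if rank > best_rank:
            best, best_rank = cand, rank
        if best_rank == 2:
            break
    return best


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full cascade; writes all outputs under ``cfg.outdir``.

    Returns the run report (cascade rows, annotation summary, DE calls,
    target coverage, context statistics, manifest).  Deterministic:
    rerunning with an identical config reproduces identical outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(cfg.genome)
    contaminants = read_fasta(cfg.contaminants)
    reference = read_fasta(cfg.reference)

    cascade_rows: list[dict] = []

    def log(stage: str, leaf: int, bud: int) -> None:
        cascade_rows.append({"stage": stage, "leaf": leaf, "bud": bud})

    # --- preprocessing -------------------------------------------------
    raw_leaf = list(iter_reads(cfg.leaf))
    raw_bud = list(iter_reads(cfg.bud))
    log("raw reads", len(raw_leaf), len(raw_bud))
    leaf_kept, leaf_stats = size_filter(raw_leaf, cfg.preprocess)
    bud_kept, bud_stats = size_filter(raw_bud, cfg.preprocess)
    log("size window (reads)", leaf_stats["retained"], bud_stats["retained"])
    rs = collapse_and_count(leaf_kept, bud_kept)
    rs, removed = remove_contaminants(rs, contaminants, cfg.preprocess)
    log("contaminant (reads removed)", removed["leaf"], removed["bud"])
    rs.write_tsv(out / "collapsed.tsv")

    # --- genome mapping and repeat filter ------------------------------
    hits, repeat_flagged = map_reads(rs.sequences(), genome, cfg.search)
    log(
        "repeat-derived, >%d hits (reads removed)" % cfg.search.max_hits,
        sum(rs.count(s, 0) for s in repeat_flagged),
        sum(rs.count(s, 1) for s in repeat_flagged),
    )
    mappable = [s for s in rs.sequences() if s not in repeat_flagged]

    # --- conserved / remainder split -----------------------------------
    conserved_fams, remainder = match_known_mirnas(mappable, reference, cfg.search)
    log(
        "known-miRNA homolog (reads)",
        sum(rs.count(s, 0) for s in conserved_fams),
        sum(rs.count(s, 1) for s in conserved_fams),
    )
    log(
        "non-conserved sRNA (reads)",
        sum(rs.count(s, 0) for s in remainder),
        sum(rs.count(s, 1) for s in remainder),
    )
    log(
        "non-conserved sRNA (unique sequences)",
        sum(1 for s in remainder if rs.count(s, 0) > 0),
        sum(1 for s in remainder if rs.count(s, 1) > 0),
    )

    # --- conserved branch ----------------------------------------------
    cons_groups = group_length_variants(rs, sequences=conserved_fams.keys())
    cons_cands: list[Candidate] = []
    for gi, grp in enumerate(cons_groups):
        seq = grp.representative
        cand = _choose_candidate(seq, hits.get(seq, []), genome, rs, cfg)
        if cand is None:
            continue
        cons_cands.append(
            _candidate(f"con_{gi + 1:04d}", grp, cand, rs, family=conserved_fams[seq])
        )
    conserved_ann = annotate_conserved(cons_cands, cfg.annotate)

    # --- non-conserved branch ------------------------------------------
    # the acceptance rule requires an exact genomic anchor, at most
    # max_hits occurrences and >= r_min reads; the count screen runs
    # first because the filters are conjunctive and folding is the
    # expensive step.
    nc_groups = group_length_variants(rs, sequences=remainder)
    nc_cands: list[Candidate] = []
    n_pass_star = [0, 0]
    for gi, grp in enumerate(nc_groups):
        if max(grp.count_leaf, grp.count_bud) < cfg.annotate.r_min:
            continue
        seq = grp.representative
        exact = [h for h in hits.get(seq, []) if h.n_mismatches == 0]
        if not exact:
            continue
        cand = _choose_candidate(seq, exact, genome, rs, cfg)
        if cand is None:
            continue
        nc_cands.append(_candidate(f"nc_{gi + 1:04d}", grp, cand, rs))
        if cand.report and cand.report.passed and any(cand.star_observed):
            if grp.count_leaf > 0:
                n_pass_star[0] += 1
            if grp.count_bud > 0:
                n_pass_star[1] += 1
    log("hairpin pass with star (unique sequences)", *n_pass_star)
    nonconserved_ann = annotate_nonconserved(nc_cands, cfg.annotate)

    annotations = conserved_ann + nonconserved_ann
    ann_df = annotations_to_frame(annotations)
    ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
    write_gff3(out / "annotations.gff3", annotations)
    stats = family_stats(annotations)

    # --- differential expression ---------------------------------------
    by_id = {c.id: c for c in cons_cands + nc_cands}
    if cfg.de_counting == "dominant":
        counts = [
            (a.id, by_id[a.id].dominant_count_leaf, by_id[a.id].dominant_count_bud)
            for a in annotations
        ]
    else:
        counts = [(a.id, a.count_leaf, a.count_bud) for a in annotations]
    test = {"ma": ma_test, "fisher": fisher_test, "lrt": lr_test}[cfg.de_method]
    if counts:
        ids, c1, c2 = zip(*counts)
        de = test(list(c1), list(c2), rs.n_leaf, rs.n_bud)
        de.insert(0, "id", ids)
        up_bud_idx, up_leaf_idx, de = call_de(de, alpha=cfg.de_alpha)
        up_bud = de.loc[up_bud_idx, "id"].tolist()
        up_leaf = de.loc[up_leaf_idx, "id"].tolist()
    else:
        de = pd.DataFrame()
        up_bud, up_leaf = [], []
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)

    # --- targets ---------------------------------------------------------
    target_report: dict = {}
    if cfg.cds:
        cds = read_fasta(cfg.cds)
        mirnas = {a.id: a.mature_seq for a in annotations}
        t_hits = find_targets(mirnas, cds, cfg.scoring)
        hits_to_frame(t_hits).to_csv(out / "targets.tsv", sep="\t", index=False)
        with_target = {h.mirna_id for h in t_hits}
        for cls, anns in (
            ("conserved", conserved_ann),
            ("non-conserved", nonconserved_ann),
        ):
            n_with = sum(1 for a in anns if a.id in with_target)
            target_report[cls] = {
                "n_with_target": n_with,
                "n_total": len(anns),
                "percent": target_coverage_percent(n_with, len(anns)),
            }

    # --- genomic context --------------------------------------------------
    context_report: dict = {}
    if len(ann_df):
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        obs = chromosome_counts(ann_df.rename(columns={"chrom": "chrom"}), list(genome))
        if sum(obs.values()) > 0 and len(obs) >= 2:
            g, p = g_test(obs, chrom_lengths=chrom_lengths, model="length")
            context_report["g_test"] = {"G": g, "p": p, "observed": obs}
        if cfg.qtl:
            qtls = read_bed(cfg.qtl)
            overlap, fam_tally, flagged = colocalize(
                ann_df[["id", "family", "chrom", "start", "end"]],
                qtls,
                chrom_namespace=set(genome),
            )
            overlap.to_csv(out / "qtl_overlap.tsv", sep="\t", index=False)
            fam_tally.to_csv(out / "qtl_families.tsv", sep="\t", index=False)
            context_report["qtl"] = {
                "n_colocalized": int(overlap["id"].nunique()) if len(overlap) else 0,
                "n_families": int(len(fam_tally)),
                "flagged": flagged,
            }

    cascade = pd.DataFrame(cascade_rows)
    cascade.to_csv(out / "cascade.tsv", sep="\t", index=False)

    report = {
        "cascade": cascade_rows,
        "annotation": {
            "n_conserved": len(conserved_ann),
            "n_nonconserved": len(nonconserved_ann),
            "total": len(annotations),
            "family_sizes": stats["family_sizes"],
            "tissue": stats["tissue"],
        },
        "de": {"method": cfg.de_method, "up_in_bud": up_bud, "up_in_leaf": up_leaf},
        "targets": target_report,
        "context": context_report,
        "manifest": {
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _candidate(
    cid: str, grp: VariantGroup, cand: HairpinCandidate, rs: SmallReadSet, family: str = ""
) -> Candidate:
    seq = grp.representative
    return Candidate(
        id=cid,
        sequence=seq,
        hairpin=cand,
        count_leaf=grp.count_leaf,
        count_bud=grp.count_bud,
        family=family,
        dominant_count_leaf=rs.count(seq, 0),
        dominant_count_bud=rs.count(seq, 1),
    )


def write_gff3(path: str | Path, annotations: list[MiRNAAnnotation]) -> None:
    """Annotations as GFF3 (1-based inclusive) with mature child features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = (
                f"ID={a.id};class={a.cls};family={a.family or 'NA'};"
                f"tier={a.tier};tissue={a.tissue}"
            )
            fh.write(
                f"{a.chrom}\tmirseed\tmiRNA\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\t{attrs}\n"
            )
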