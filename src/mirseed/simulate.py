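"""Synthetic small-RNA study generator.

Emits a toy genome with planted miRNA loci, two read libraries ("leaf"
and "bud"), a contaminant set, a known-miRNA reference set, QTL
intervals and a ground-truth table, with the statistical structure the
downstream analysis assumes:

* hairpin loci whose mature and star sit on opposite arms of a perfect
  fold-back with a 2-nt 3' overhang duplex;
* conserved loci within a bounded substitution distance of a reference
  mature sequence, novel loci unrelated to any reference, and repeat
  loci copied to more than ten genomic positions;
* per-locus abundances log-uniform over [10, 5000] reads, bud/leaf fold
  changes for a subset of loci, dominant-length reads with +/-1-nt end
  variants, star reads for a configurable fraction of loci;
* a background of genome-derived degradation fragments with a bimodal
  21/24-nt length distribution, plus contaminant-derived reads.

Counts are drawn per locus as Poisson around abundance x depth-scale
(x fold change in the bud library), so planted fold changes survive as
count ratios; library totals therefore fluctuate around ``lib_sizes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .context import QTLInterval, write_bed
from .seqs import revcomp, to_dna, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_TARGET = {"G": "T", "T": "G"}  # miRNA base -> target base forming G:U
_MISMATCH_TARGET = {"A": "C", "C": "T", "G": "A", "T": "C"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults are a desk-scale rendition of a two-tissue plant small-RNA
    experiment: two libraries of ~20k reads, a multi-chromosome toy
    genome, per-locus abundances log-uniform over [10, 5000] reads, a
    bimodal 21/24-nt read-length background, ~0.5% contaminant reads,
    star reads for about two thirds of loci, and a handful of loci with
    an 8-fold bud/leaf expression change.
    """

    seed: int = 0
    n_conserved_loci: int = 20
    n_novel_loci: int = 15
    n_repeat_loci: int = 3
    repeat_copies: int = 12  # > 10 so the multi-hit filter fires
    genome_length: int = 64_000
    n_chromosomes: int = 8
    lib_sizes: tuple[int, int] = (20_000, 20_000)  # (leaf, bud) expected depth
    len_mix: float = 0.55  # weight of the 21-nt vs the 24-nt background mode
    star_read_fraction: float = 0.65
    de_up_loci: int = 3  # loci induced in bud at de_fold
    de_down_loci: int = 2  # loci repressed in bud at 1/de_fold
    de_fold: float = 8.0
    fold_changes: tuple[float, ...] | None = None  # explicit per-locus override
    background_read_fraction: float = 0.15
    contaminant_read_fraction: float = 0.005
    mutation_rate_conserved: float = 0.05  # subs/nt vs reference, capped at 2
    abundance_range: tuple[float, float] = (10.0, 5000.0)
    loop_length: int = 8
    locus_spacing: int = 350  # min distance between planted cores
    edge_margin: int = 170  # keeps precursors clear of contig edges

    def __post_init__(self) -> None:
        for name in (
            "len_mix",
            "star_read_fraction",
            "background_read_fraction",
            "contaminant_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.lib_sizes) <= 0:
            raise ValueError("lib_sizes must be positive")


@dataclass
class LocusTruth:
    locus_id: str
    cls: str  # conserved | novel | repeat
    family: str
    chrom: str
    strand: str
    start: int  # mature genomic interval, 0-based half-open
    end: int
    mature_seq: str  # strand-corrected (the sequence reads carry)
    star_start: int
    star_end: int
    star_seq: str
    abundance: float
    fold_change: float
    emits_star: bool
    count_leaf: int = 0  # realized mature reads (all length variants)
    count_bud: int = 0
    star_count_leaf: int = 0
    star_count_bud: int = 0


@dataclass
class HairpinLocus:
    """A planted precursor with its structural ground truth."""

    precursor: str  # flank + mature + loop + star arm + flank (DNA)
    core: str  # mature + loop + star arm
    mature_offset: int  # within precursor
    mature_length: int
    star_offset: int  # within precursor (includes the 2-nt overhang)
    star_length: int
    loop: str


@dataclass
class SimResult:
    genome: dict[str, str]
    reads_leaf: list[str]
    reads_bud: list[str]
    contaminants: dict[str, str]
    reference: dict[str, str]  # known-miRNA mature set (family_member ids)
    truth: list[LocusTruth]
    qtls: list[QTLInterval]
    config: SimConfig


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_hairpin_locus(
    mature: str,
    seed: int,
    loop_length: int = 8,
    flank: int = 150,
    star_mismatches: int = 0,
) -> HairpinLocus:
    """Embed a mature sequence in a fold-back precursor with random flanks.

    The star arm is the reverse complement of the mature (optionally with
    up to ``star_mismatches`` substitutions); the duplex released from
    the stem carries a 2-nt 3' overhang on each strand, so the planted
    star interval starts 2 nt into the star arm and ends 2 nt beyond it.
    Deterministic in (mature, seed).
    """
    mature = to_dna(mature)
    if not 18 <= len(mature) <= 24:
        raise ValueError(f"mature length must be in [18, 24], got {len(mature)}")
    if loop_length < 3:
        raise ValueError("terminal loop must be at least 3 nt")
    rng = np.random.default_rng(seed)
    loop = _random_seq(rng, loop_length)
    arm = list(revcomp(mature))
    if star_mismatches:
        if star_mismatches > 3:
            raise ValueError("at most 3 star-arm mismatches supported")
        pos = rng.choice(len(arm), size=star_mismatches, replace=False)
        for p in pos:
            arm[p] = _MISMATCH_TARGET[arm[p]]
    core = mature + loop + "".join(arm)
    left = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    lm = len(mature)
    return HairpinLocus(
        precursor=left + core + right,
        core=core,
        mature_offset=flank,
        mature_length=lm,
        star_offset=flank + lm + loop_length + 2,
        star_length=lm,
        loop=loop,
    )


def _mutate(rng: np.random.Generator, seq: str, rate: float, cap: int = 2) -> str:
    n_sub = min(int(rng.binomial(len(seq), rate)), cap)
    if n_sub == 0:
        return seq
    out = list(seq)
    for p in rng.choice(len(seq), size=n_sub, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _length_weights(len_mix: float) -> dict[int, float]:
    base = {18: 0.04, 19: 0.05, 20: 0.07, 22: 0.07, 23: 0.05}
    rest = 1.0 - sum(base.values())
    base[21] = rest * len_mix
    base[24] = rest * (1.0 - len_mix)
    return base


class PlacementError(RuntimeError):
    """Raised when loci cannot be placed without overlap."""


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    size: int,
    spacing: int,
    margin: int,
    tries: int = 2000,
) -> tuple[str, int]:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        hi = chrom_lengths[chrom] - margin - size
        if hi <= margin:
            continue
        pos = int(rng.integers(margin, hi))
        ok = all(
            pos + size + spacing <= s or pos >= e + spacing
            for s, e in occupied[chrom]
        )
        if ok:
            occupied[chrom].append((pos, pos + size))
            return chrom, pos
    raise PlacementError(
        f"could not place a {size}-nt locus after {tries} tries; "
        "increase genome_length or reduce locus counts/spacing"
    )


def simulate_libraries(cfg: SimConfig | None = None) -> SimResult:
    """Generate the full synthetic study (deterministic in the config)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    chrom_len = cfg.genome_length // cfg.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome_arr = {c: rng.choice(_BASES, size=chrom_len).copy() for c in chroms}
    chrom_lengths = {c: chrom_len for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    n_loci = cfg.n_conserved_loci + cfg.n_novel_loci
    # per-locus fold changes (bud/leaf)
    if cfg.fold_changes is not None:
        if len(cfg.fold_changes) != n_loci:
            raise ValueError("fold_changes must have one entry per non-repeat locus")
        folds = np.array(cfg.fold_changes, dtype=float)
    else:
        folds = np.ones(n_loci)
        de_idx = rng.choice(n_loci, size=cfg.de_up_loci + cfg.de_down_loci, replace=False)
        folds[de_idx[: cfg.de_up_loci]] = cfg.de_fold
        folds[de_idx[cfg.de_up_loci :]] = 1.0 / cfg.de_fold

    lo, hi = cfg.abundance_range
    abundance = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_loci))
    # differential loci get mid-range abundances so their expected counts
    # are comfortably testable
    abundance[folds != 1.0] = rng.uniform(400.0, 800.0, size=(folds != 1.0).sum())

    # conserved families: ~70% founders, the rest join an existing family
    n_cons = cfg.n_conserved_loci
    n_founders = max(1, int(round(n_cons * 0.7)))
    family_idx = list(range(n_founders)) + [
        int(rng.integers(0, n_founders)) for _ in range(n_cons - n_founders)
    ]

    truth: list[LocusTruth] = []
    reference: dict[str, str] = {}
    family_members: dict[str, int] = {}

    def plant_hairpin(idx: int, cls: str, family: str, mature: str | None = None) -> LocusTruth:
        if mature is None:
            mlen = int(rng.choice([20, 21, 22], p=[0.15, 0.7, 0.15]))
            mature = _random_seq(rng, mlen)
        hp = build_hairpin_locus(
            mature, seed=int(rng.integers(0, 2**31 - 1)), loop_length=cfg.loop_length
        )
        core = hp.core
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pos = _place(
            rng, occupied, chrom_lengths, len(core), cfg.locus_spacing, cfg.edge_margin
        )
        arr = genome_arr[chrom]
        inserted = core if strand == "+" else revcomp(core)
        arr[pos : pos + len(core)] = np.frombuffer(inserted.encode(), dtype=np.uint8)
        lc = len(core)
        lm = hp.mature_length
        # relative intervals on the core (5'->3' of the planted strand)
        m_rel = (0, lm)
        s_rel = (lm + cfg.loop_length + 2, lc + 2)  # 2-nt 3' overhang into flank
        if strand == "+":
            m_iv = (pos + m_rel[0], pos + m_rel[1])
            s_iv = (pos + s_rel[0], pos + s_rel[1])
        else:
            m_iv = (pos + lc - m_rel[1], pos + lc - m_rel[0])
            s_iv = (pos + lc - s_rel[1], pos + lc - s_rel[0])
        return LocusTruth(
            locus_id=f"{cls}_{idx:03d}",
            cls=cls,
            family=family,
            chrom=chrom,
            strand=strand,
            start=m_iv[0],
            end=m_iv[1],
            mature_seq=mature,
            star_start=s_iv[0],
            star_end=s_iv[1],
            star_seq="",  # filled after all insertions (flank bases involved)
            abundance=float(abundance[idx]),
            fold_change=float(folds[idx]),
            emits_star=bool(rng.random() < cfg.star_read_fraction),
        )

    founder_mature: dict[str, str] = {}
    for i in range(n_cons):
        fam = f"miR{family_idx[i] + 1:04d}"
        if fam in founder_mature:
            # later family members stay within the homology budget of the
            # family reference: 1-2 substitutions from it, distinct from it
            base = reference[f"{fam}_a"]
            mature = base
            while mature == base:
                mature = _mutate(rng, base, 0.08, cap=2)
            t = plant_hairpin(i, "conserved", fam, mature=mature)
        else:
            t = plant_hairpin(i, "conserved", fam)
            founder_mature[fam] = t.mature_seq
            reference[f"{fam}_a"] = _mutate(
                rng, t.mature_seq, cfg.mutation_rate_conserved
            )
        truth.append(t)
        family_members[fam] = family_members.get(fam, 0) + 1
    for i in range(cfg.n_novel_loci):
        truth.append(plant_hairpin(n_cons + i, "novel", ""))
    # decoy reference families with no planted locus
    for d in range(5):
        reference[f"miR9{d:03d}_a"] = _random_seq(rng, 21)

    # repeat loci: a 21-nt seed copied to many positions
    for r in range(cfg.n_repeat_loci):
        seed_seq = _random_seq(rng, 21)
        first: tuple[str, int] | None = None
        for _ in range(cfg.repeat_copies):
            chrom, pos = _place(rng, occupied, chrom_lengths, 21, 40, cfg.edge_margin)
            genome_arr[chrom][pos : pos + 21] = np.frombuffer(
                seed_seq.encode(), dtype=np.uint8
            )
            if first is None:
                first = (chrom, pos)
        assert first is not None
        truth.append(
            LocusTruth(
                locus_id=f"repeat_{r:03d}",
                cls="repeat",
                family="repeat",
                chrom=first[0],
                strand="+",
                start=first[1],
                end=first[1] + 21,
                mature_seq=seed_seq,
                star_start=0,
                star_end=0,
                star_seq="",
                abundance=float(np.exp(rng.uniform(np.log(50.0), np.log(500.0)))),
                fold_change=1.0,
                emits_star=False,
            )
        )

    genome = {c: genome_arr[c].tobytes().decode() for c in chroms}

    # fill star sequences now that every insertion (and its flanks) is final
    for t in truth:
        if t.cls == "repeat":
            continue
        segment = genome[t.chrom][t.star_start : t.star_end]
        t.star_seq = segment if t.strand == "+" else revcomp(segment)

    # contaminant sequences (rRNA/tRNA/snoRNA/organellar stand-ins)
    contaminants = {
        name: _random_seq(rng, int(rng.integers(80, 161)))
        for name in ["rRNA_1", "rRNA_2", "tRNA_1", "tRNA_2", "snoRNA_1", "chloroplast_1"]
    }

    # ---- read emission -------------------------------------------------
    usable = 1.0 - cfg.background_read_fraction - cfg.contaminant_read_fraction
    base_total = abundance.sum() + sum(t.abundance for t in truth if t.cls == "repeat")
    if base_total > 0:
        scales = [cfg.lib_sizes[i] * usable / base_total for i in (0, 1)]
    else:
        scales = [0.0, 0.0]

    reads: list[list[str]] = [[], []]
    lw = _length_weights(cfg.len_mix)
    lens = np.array(sorted(lw))
    lprobs = np.array([lw[l] for l in sorted(lw)])
    lprobs /= lprobs.sum()

    def emit_locus(t: LocusTruth) -> None:
        g = genome[t.chrom]
        if t.strand == "+":
            dominant = g[t.start : t.end]
            plus_one = g[t.start : t.end + 1]
        else:
            dominant = revcomp(g[t.start : t.end])
            plus_one = revcomp(g[t.start - 1 : t.end])
        minus_one = dominant[:-1]
        for lib in (0, 1):
            fc = t.fold_change if lib == 1 else 1.0
            mean = t.abundance * fc * scales[lib]
            total = int(rng.poisson(mean))
            if t.cls == "repeat":
                reads[lib].extend([dominant] * total)
                if lib == 0:
                    t.count_leaf = total
                else:
                    t.count_bud = total
                continue
            n_dom, n_plus, n_min = rng.multinomial(total, [0.82, 0.11, 0.07])
            reads[lib].extend(
                [dominant] * n_dom + [plus_one] * n_plus + [minus_one] * n_min
            )
            if lib == 0:
                t.count_leaf = total
            else:
                t.count_bud = total
            if t.emits_star:
                n_star = int(rng.poisson(0.12 * mean))
                reads[lib].extend([t.star_seq] * n_star)
                if lib == 0:
                    t.star_count_leaf = n_star
                else:
                    t.star_count_bud = n_star

    for t in truth:
        emit_locus(t)

    # genome-derived background fragments, bimodal 21/24-nt lengths
    for lib in (0, 1):
        n_bg = int(rng.poisson(cfg.background_read_fraction * cfg.lib_sizes[lib]))
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.choice(lens, p=lprobs))
            pos = int(rng.integers(0, chrom_len - length))
            frag = genome[chrom][pos : pos + length]
            reads[lib].append(frag if rng.random() < 0.5 else revcomp(frag))
        n_cont = int(rng.poisson(cfg.contaminant_read_fraction * cfg.lib_sizes[lib]))
        cnames = list(contaminants)
        for _ in range(n_cont):
            cseq = contaminants[cnames[int(rng.integers(0, len(cnames)))]]
            length = int(rng.choice(lens, p=lprobs))
            pos = int(rng.integers(0, len(cseq) - length))
            reads[lib].append(cseq[pos : pos + length])

    for lib in (0, 1):
        order = rng.permutation(len(reads[lib]))
        reads[lib] = [reads[lib][i] for i in order]

    # QTL intervals: two anchored on planted loci, two elsewhere
    qtls: list[QTLInterval] = []
    planted = [t for t in truth if t.cls != "repeat"]
    labels = iter(["CR-QTL_1", "BD-QTL_1", "CR-QTL_2", "BD-QTL_2"])
    if planted:
        anchors = rng.choice(len(planted), size=min(2, len(planted)), replace=False)
        for ai in anchors:
            t = planted[int(ai)]
            s = max(0, t.start - 1500)
            e = min(chrom_len, t.end + 1500)
            qtls.append(QTLInterval(t.chrom, s, e, next(labels)))
    qtl_len = min(3000, chrom_len // 2)
    for _ in range(2):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, max(1, chrom_len - qtl_len)))
        qtls.append(QTLInterval(chrom, s, s + qtl_len, next(labels)))

    return SimResult(
        genome=genome,
        reads_leaf=reads[0],
        reads_bud=reads[1],
        contaminants=contaminants,
        reference=reference,
        truth=truth,
        qtls=qtls,
        config=cfg,
    )


# ---- engineered target sites ------------------------------------------


def _decompose_score(mirna: str, score: float, region: tuple[int, int]) -> list[tuple[int, str]]:
    """Edits (1-based position, 'wobble'|'mismatch') realizing a penalty score.

    Uses outside-region wobbles (0.5), inside-region mismatches (2.0) and
    outside-region mismatches (1.0).  Raises ValueError when the score is
    not reachable on this miRNA.
    """
    if score < 0 or (score * 2) != int(score * 2):
        raise ValueError("scores must be non-negative multiples of 0.5")
    m = len(mirna)
    lo, hi = region
    outside = [p for p in range(m, 0, -1) if not lo <= p <= hi]
    inside = [p for p in range(lo, min(hi, m) + 1)]
    edits: list[tuple[int, str]] = []
    rem = score
    if rem * 2 % 2 == 1:  # fractional half: one outside wobble
        wpos = [p for p in outside if mirna[p - 1] in "GT"]
        if not wpos:
            raise ValueError("no outside G/U position available for a 0.5 wobble")
        p = wpos[0]
        edits.append((p, "wobble"))
        outside.remove(p)
        rem -= 0.5
    while rem >= 2.0 and inside:
        edits.append((inside.pop(), "mismatch"))
        rem -= 2.0
    while rem >= 1.0 and outside:
        edits.append((outside.pop(0), "mismatch"))
        rem -= 1.0
    if rem > 0:
        raise ValueError(f"score {score} not reachable for a {m}-nt miRNA")
    return edits


def simulate_cds_with_sites(
    mirnas: dict[str, str],
    scores: list[float],
    seed: int,
    flank: int = 30,
    region: tuple[int, int] = (2, 13),
) -> tuple[dict[str, str], pd.DataFrame]:
    """CDS set with one engineered complementary site per (miRNA, score).

    Each CDS embeds a site whose recomputed complementarity penalty under
    the default scheme equals the intended score (verified at build time).
    Returns ({cds_id: sequence}, truth table with site coordinates).
    """
    from .targets import ScoringScheme, _align_one

    if len(mirnas) != len(scores):
        raise ValueError("need one intended score per miRNA")
    rng = np.random.default_rng(seed)
    scheme = ScoringScheme(region=region)
    cds: dict[str, str] = {}
    rows = []
    for k, (mid, mseq) in enumerate(sorted(mirnas.items())):
        mseq = to_dna(mseq)
        score = float(scores[k])
        site_3to5 = [_WC[b] for b in mseq]
        for pos, kind in _decompose_score(mseq, score, region):
            b = mseq[pos - 1]
            site_3to5[pos - 1] = _WOBBLE_TARGET[b] if kind == "wobble" else _MISMATCH_TARGET[b]
        site = "".join(reversed(site_3to5))  # 5'->3' on the CDS
        for attempt in range(20):
            seq = _random_seq(rng, flank) + site + _random_seq(rng, flank)
            res = _align_one(mseq, seq, scheme)
            assert res is not None
            if np.isclose(res[0], score):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("random flanks kept producing a better site")
        cid = f"CDS_{k:04d}"
        cds[cid] = seq
        rows.append(
            {
                "cds": cid,
                "mirna": mid,
                "intended_score": score,
                "site_start": flank,
                "site_end": flank + len(site),
            }
        )
    return cds, pd.DataFrame(rows)


# ---- writers -----------------------------------------------------------


def truth_to_frame(truth: list[LocusTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


def write_simulation(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, leaf.fa, bud.fa, contaminants.fa, known_mirnas.fa,
    qtl.bed and truth.tsv; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "leaf": out / "leaf.fa",
        "bud": out / "bud.fa",
        "contaminants": out / "contaminants.fa",
        "reference": out / "known_mirnas.fa",
        "qtl": out / "qtl.bed",
        "truth": out / "truth.tsv",
    }
    write_fasta(paths["genome"], sim.genome.items())
    write_fasta(paths["leaf"], ((f"leaf_{i + 1}", s) for i, s in enumerate(sim.reads_leaf)))
    write_fasta(paths["bud"], ((f"bud_{i + 1}", s) for i, s in enumerate(sim.reads_bud)))
    write_fasta(paths["contaminants"], sim.contaminants.items())
    write_fasta(paths["reference"], sim.reference.items())
    write_bed(paths["qtl"], sim.qtls)
    truth_to_frame(sim.truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths
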