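# Methods

This note documents the models and procedures implemented in `mirseed`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Problem setting

Two small-RNA libraries (here called *leaf* and *bud*, one library per
condition, no replicates) are sequenced from a plant with a reference
genome. The goal is to annotate miRNA loci — conserved homologs of known
families and novel ("non-conserved") loci — and then to characterize
them: expression differences between the two libraries, candidate target
transcripts, and co-localization with QTL intervals.

## Read cleaning

Reads are kept if their length falls in a configurable window (default
18–24 nt) and they contain only ACGT/U; surviving reads are collapsed to
unique sequences with per-library counts. A read is removed as a
contaminant when it occurs as a full-length substring of any sequence in
the contaminant set (rRNA/tRNA/snoRNA/organellar), on either strand,
with at most `contaminant_max_mismatch` substitutions (default 0). At
query lengths of 18–24 nt a deterministic containment scan is exact and
reproducible, which is why no heuristic aligner is used here.

Length variants — sequences related by end-trims/extensions of at most
2 nt per end, transitively closed — are grouped; the group
representative is the variant with the highest total count (ties: the
longer variant, then the lexicographically smaller). Downstream
expression uses either the group total (default) or the representative
("dominant-variant") counts.

## Genome anchoring and the repeat filter

All searches are substitution-only Hamming scans over both strands,
complete by construction (every window is checked). Budgets: 2
substitutions for matching reads to known mature miRNAs (with ±2 nt
length slack via containment), 2 for genome mapping, 0 for anchoring
novel candidates. A read with more than `max_hits` (default 10) genomic
occurrences is flagged repeat-derived and excluded — strictly more
than, so a read with exactly 10 hits survives.

## Hairpin evaluation

A candidate anchored at a genomic hit is extended by `flank` nt
(default 150) on each side, reverse-complemented for minus-strand hits,
and folded.

**Folding engines.** The default engine maximizes the number of base
pairs (A:U, G:C, G:U; minimum hairpin loop 3 nt) by a Nussinov-style
dynamic program with a deterministic traceback: at each subproblem,
closing the outermost pair is preferred when co-optimal (which zips
helices), then leaving the right end unpaired, then the leftmost
co-optimal pairing partner. The rationale for base-pair maximization
over thermodynamics is that every downstream decision depends only on
hairpin topology — which bases pair with which — not on free energies,
and the DP is exact, dependency-free and deterministic. A `vienna`
engine (minimum free energy via the ViennaRNA bindings) can be selected
per run; downstream logic consumes only the dot-bracket either way.

**Best duplex chain.** A base-pair maximizer is free to pair a few
mature bases into a flank when that choice is co-optimal; on planted
perfect hairpins this affects 2–4 of the 5'-most mature bases in a
noticeable fraction of random flank contexts. Annotation criteria in
the MirCheck tradition treat such bases as imperfections (unpaired or
bulged), not as grounds for wholesale rejection. The evaluator
therefore extracts, from the mature's paired bases whose partners lie
on the majority side, the strictly antiparallel subchain minimizing
dropped bases plus bulge penalties, and measures all criteria against
that chain. If the mature pairs mostly with itself, it spans the
terminal loop and fails outright.

**Criteria** (defaults in parentheses; all configurable): mature bases
outside the duplex chain ≤ 4; asymmetric bulge nucleotides within the
duplex ≤ 2; duplex mismatches (symmetric internal-loop positions) ≤ 4;
mature not spanning the loop; and a predictable star. On 200 random
genomic windows with no planted hairpin, about 1% pass — the criteria,
not the folder, carry the specificity.

**Star geometry.** The star is the interval pairing with the mature,
shifted so both duplex 3' ends carry a 2-nt overhang (the geometry of a
Dicer product): with the duplex locally perfect around chain pair
(i, p), the partner of mature position x extrapolates to p − (x − i),
and the star spans the extrapolated partners of (mature 3' end − 2) and
(mature 5' end) + 2. On perfect duplexes this map is an involution:
the star of the star is the mature. A star is "observed" in a library
when some read equals the predicted star sequence exactly or within a
±1 nt end shift.

**A caveat on strand symmetry.** Criteria verdicts are *not* exactly
invariant under reverse-complementing the precursor: reverse
complementation maps a G:U wobble to A:C, which cannot pair, so folds
differ. The invariance holds for Watson–Crick-only stems and is tested
there.

## Annotation

Conserved candidates (known-family homologs that passed the hairpin)
are accepted in evidence tiers, in order: (1) star sequenced in either
library — *biogenesis*; (2) expression in both libraries, or at least
`strong_accum` (default 10) reads in one — *expression-ancillary*;
(3) an already-accepted member of the same family — *family-ancillary*
(iterated to a fixed point, so input order is irrelevant);
(4) an externally curated conservation flag — *conservation-ancillary*.
Families suspected to be repeat-derived can be listed as
repeat-flagged, restricting them to tier (1). The `strong_accum`
quantification is this artifact's choice; tier ordering formalizes
criteria that are usually applied narratively.

Non-conserved candidates require the full biogenesis case: hairpin
pass, star sequenced in at least one library, and at least `r_min`
(default 2) reads in at least one library. "At least one" rather than
"both" is deliberate: the stricter reading would exclude genuine
tissue-specific miRNAs with zero reads in one library. The count screen
runs before folding; the filters are conjunctive, so ordering does not
change the accepted set, and it avoids folding thousands of background
singletons.

Tissue specificity is count-based: zero reads in exactly one library.

## Target scoring

A miRNA is aligned 5'→3' against each CDS read 3'→5' (semi-global: the
miRNA in full, the site floating). Penalties per miRNA position:
Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap 2, each doubled at
miRNA positions 2–13 from the 5' end; at most one gap per alignment
(insertions take the multiplier of the next miRNA position). The DP is
layered by gap count and exact; it was checked against exhaustive
alignment enumeration. Sites with score strictly below `max_score`
(default 4) are reported, the minimal-score site per (miRNA, CDS) pair.
The constants follow the published convention of the classical plant
target-prediction scheme; the threshold's strictness is configurable.
No hybridization-energy term is computed.

## Differential expression

Counts are modelled as binomial draws from library totals. The MA-plot
test: with X = log₂C₁, Y = log₂C₂ (zero counts floored to 1 inside the
log only), M = X − Y, A = (X + Y)/2, and pooled p̂ = (C₁+C₂)/(n₁+n₂),
the delta method gives E X ≈ log₂(n₁p̂), Var X ≈ (1−p̂)/(n₁p̂ ln²2)
(likewise Y), and conditioning the bivariate normal (M, A) on the
observed A yields

E(M|A) = μ_M + 2(σ²_X − σ²_Y)/(σ²_X + σ²_Y) · (A − μ_A),
Var(M|A) = 4σ²_Xσ²_Y/(σ²_X + σ²_Y),

z = (M − E(M|A))/√Var(M|A), two-sided normal p. These closed forms were
verified against numerical double integration of the conditional
density on random cases (exact agreement). Under a simulated binomial
null (2,000 features, counts ~20–2,000) the test rejects at 5.8% for
α = 0.05 — within the calibration band expected of a delta-method
normal approximation at these depths; calibration degrades below ~20
expected counts.

Fisher's exact test (two-sided, on [[C₁, n₁−C₁], [C₂, n₂−C₂]]) and the
binomial likelihood-ratio test (G², χ² with 1 df, 0·log 0 = 0 at
boundaries) are provided as alternatives. Calls use Benjamini–Hochberg
at α = 0.05 by default (the choice of α and adjustment is artifact
policy — no threshold is inherited from anywhere); direction is the
sign of M after centering by log₂(n₁/n₂).

Because the two libraries are single samples, composition effects are
real: strongly induced loci inflate one library's total and make
everything else look relatively down. This is a property of the model
(proportions, not absolute abundances) and is left visible rather than
normalized away.

## Genomic context

The G-test, G = 2ΣOᵢ ln(Oᵢ/Eᵢ) against χ² with k−1 df, asks whether
annotated loci distribute across chromosomes as expected; the default
expectation is proportional to chromosome length, with uniform as the
alternative (which null is appropriate depends on the question, so both
are exposed). QTL co-localization is interval intersection with
half-open semantics (≥1 bp overlap); QTL intervals are user-supplied
BED — no genetic-to-physical projection is attempted.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth with the statistical structure the
pipeline assumes: perfect-duplex hairpin loci (mature + ≥3 nt loop +
reverse-complement star arm, 2-nt 3' overhang duplex) on both strands
of a multi-chromosome genome; conserved loci within 2 substitutions of
a reference mature set, later family members within 2 substitutions of
the family reference; novel loci unrelated to any reference; repeat
seeds copied to 12 positions (the multi-hit filter must fire); locus
abundances log-uniform over [10, 5000] reads; dominant-length reads
plus ±1 nt 3' variants (82/11/7%); star reads at ~12% of the mature
rate for ~65% of loci; genome-derived background fragments with a
bimodal 21/24-nt length mix; ~0.5% contaminant-derived reads; and a
few loci at 8-fold bud/leaf change (both directions). Per-locus counts
are Poisson around abundance × depth-scale (× fold change in bud), so
planted fold changes survive as count ratios; library totals fluctuate
around the configured expected depths. Default scale: 2 × ~20k reads,
8 × 8 kb chromosomes, 20 + 15 + 3 loci — sizes chosen so a full run
takes seconds, not hours.

It does **not** emulate: sequencing error or quality strings, adapter
contamination, color-space artifacts, imperfect hairpins (bulged or
wobble-containing planted duplexes), transcription from overlapping
loci, or realistic genome composition (flanks are i.i.d. uniform).
Passing the plant-and-recover suite therefore shows the pipeline's
logic is correct and self-consistent, not that its thresholds are
well-tuned for real tissue libraries.

## Degenerate inputs and tie-breaks

Precursors shorter than 2×mature+loop fail folding with an explicit
verdict; hits within a flank of a contig edge are clipped and flagged;
empty contaminant sets are a no-op with a warning count; C₁ = C₂ = 0
features are untestable (p = 1, flagged); all-zero observed counts are
an error for the G-test. All orderings (hit lists, variant groups,
annotation output, target hits) have total, documented sort keys, and
every stochastic step flows from one seeded generator: identical
configurations reproduce byte-identical outputs.
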