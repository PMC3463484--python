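"""Precursor extraction, star duplex geometry and hairpin criteria."""

import numpy as np
import pytest

from mirseed.fold import FoldResult, pairs_to_dotbracket
from mirseed.hairpin import (
    HairpinCandidate,
    HairpinConfig,
    detect_star_reads,
    evaluate_candidate,
    evaluate_criteria,
    extract_precursor,
    predict_star,
)
from mirseed.patmatch import GenomicHit
from mirseed.preprocess import SmallReadSet
from mirseed.seqs import revcomp
from mirseed.simulate import build_hairpin_locus

MATURE = "ACGTACGTACGTACGTACGTA"  # 21 nt, Watson-Crick-complementable


def stub_fold(pair_table):
    seq = "N" * len(pair_table)
    return FoldResult(seq, pairs_to_dotbracket(pair_table), pair_table, 0.0)


def perfect_pt(n=52, span=21):
    """Perfect duplex: positions 0..span-1 pair 49..49-span+1, rest unpaired."""
    pt = [-1] * n
    for i in range(span):
        pt[i], pt[49 - i] = 49 - i, i
    return pt


# ---- extract_precursor -------------------------------------------------


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(0)
    return {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}


def test_extract_plus_strand(toy_genome):
    hit = GenomicHit("chr1", 1000, 1021, "+", 0)
    c = extract_precursor(hit, toy_genome, HairpinConfig())
    assert len(c.precursor) == 321
    assert c.mature_offset == 150
    assert c.mature_seq == toy_genome["chr1"][1000:1021]
    assert not c.clipped


def test_extract_minus_strand_is_reverse_complement(toy_genome):
    hit = GenomicHit("chr1", 1000, 1021, "-", 0)
    c = extract_precursor(hit, toy_genome, HairpinConfig())
    assert c.precursor == revcomp(toy_genome["chr1"][850:1171])
    assert c.mature_seq == revcomp(toy_genome["chr1"][1000:1021])
    assert c.mature_offset == 150


def test_extract_clipped_at_contig_edge(toy_genome):
    hit = GenomicHit("chr1", 50, 71, "+", 0)
    c = extract_precursor(hit, toy_genome, HairpinConfig())
    assert c.clipped
    assert c.mature_offset == 50  # left flank clipped to what exists


# ---- star prediction geometry -----------------------------------------


def test_star_has_two_nt_overhangs_on_perfect_duplex():
    star = predict_star(stub_fold(perfect_pt()), 0, 21)
    assert star == (31, 21)  # ends offset by exactly 2 from the pairing span


def test_star_prediction_is_involution_on_perfect_duplex():
    pt = perfect_pt()
    s_off, s_len = predict_star(stub_fold(pt), 0, 21)
    back = predict_star(stub_fold(pt), s_off, s_len)
    assert back == (0, 21)


def test_mature_side_bulge_shortens_star():
    # mature 0..20; position 10 bulged out, flanks pair cleanly
    pt = [-1] * 54
    for i in range(10):
        pt[i], pt[49 - i] = 49 - i, i
    for i in range(11, 21):
        pt[i], pt[50 - i] = 50 - i, i  # partners 39..30
    star = predict_star(stub_fold(pt), 0, 21)
    assert star == (32, 20)


def test_star_side_bulge_lengthens_star():
    pt = [-1] * 54
    for i in range(10):
        pt[i], pt[49 - i] = 49 - i, i
    for i in range(10, 21):
        pt[i], pt[48 - i] = 48 - i, i  # partners 38..28 (39 skipped)
    star = predict_star(stub_fold(pt), 0, 21)
    assert star == (30, 22)


def test_mature_spanning_loop_has_no_star():
    pt = [-1] * 40
    for i in range(9):  # mature pairs with itself across a turn
        pt[i], pt[20 - i] = 20 - i, i
    assert predict_star(stub_fold(pt), 0, 21) is None


def test_poorly_paired_mature_has_no_star():
    pt = [-1] * 52
    for i in range(8):  # only 8/21 paired: below the 60% floor
        pt[i], pt[49 - i] = 49 - i, i
    assert predict_star(stub_fold(pt), 0, 21) is None


# ---- criteria ----------------------------------------------------------


def test_perfect_hairpin_passes_with_zero_measures():
    core = MATURE + "ACACACAC" + revcomp(MATURE)
    cand = HairpinCandidate("chr1", 0, len(core), "+", core, 0, 21)
    cand = evaluate_candidate(cand, HairpinConfig())
    assert cand.report.passed
    assert cand.report.unpaired_mature == 0
    assert cand.report.asymmetric_bulge == 0
    assert cand.report.duplex_mismatches == 0
    assert cand.star_seq is not None


def test_too_many_unpaired_mature_bases_fails():
    pt = [-1] * 52
    for i in range(16):  # 5 unpaired > default threshold 4
        pt[i], pt[49 - i] = 49 - i, i
    report, _ = evaluate_criteria(stub_fold(pt), 0, 21)
    assert not report.passed
    assert report.unpaired_mature == 5
    assert "unpaired_mature" in report.reason


def test_short_precursor_fails_fold():
    cand = HairpinCandidate("chr1", 0, 30, "+", "ACGT" * 7 + "AC", 0, 21)
    cand = evaluate_candidate(cand)
    assert not cand.report.passed
    assert "fail-fold" in cand.report.reason


def test_verdict_invariant_under_reverse_complement_wc_stem():
    core = MATURE + "ACACACAC" + revcomp(MATURE)
    fwd = evaluate_candidate(HairpinCandidate("c", 0, len(core), "+", core, 0, 21))
    rc = revcomp(core)
    rev = evaluate_candidate(
        HairpinCandidate("c", 0, len(core), "-", rc, len(core) - 21, 21)
    )
    for attr in ("passed", "unpaired_mature", "asymmetric_bulge", "duplex_mismatches"):
        assert getattr(fwd.report, attr) == getattr(rev.report, attr)


def test_random_windows_rarely_pass():
    """Criteria specificity: random genomic windows pass at well under 10%."""
    rng = np.random.default_rng(0)
    n_pass = 0
    n = 200
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGT"), 321))
        cand = evaluate_candidate(HairpinCandidate("c", 0, 321, "+", seq, 150, 21))
        n_pass += cand.report.passed
    assert n_pass / n < 0.10


# ---- star read detection ----------------------------------------------


@pytest.fixture(scope="module")
def planted_candidate():
    # non-periodic mature: an ACGT-repeat would pair in ambiguous registers
    hp = build_hairpin_locus("GCTTAAAAGCCATGGAATCTT", seed=4)
    cand = HairpinCandidate(
        "chr1", 0, len(hp.precursor), "+", hp.precursor, hp.mature_offset, hp.mature_length
    )
    cand = evaluate_candidate(cand, HairpinConfig())
    assert cand.report.passed
    return hp, cand


def test_star_reads_detected_per_library(planted_candidate):
    hp, cand = planted_candidate
    star = hp.precursor[hp.star_offset : hp.star_offset + hp.star_length]
    rs = SmallReadSet(counts={star: (0, 3)}, n_leaf=0, n_bud=3)
    assert detect_star_reads(cand, rs) == (False, True)


def test_shifted_star_read_detected(planted_candidate):
    hp, cand = planted_candidate
    shifted = hp.precursor[hp.star_offset + 1 : hp.star_offset + hp.star_length]
    rs = SmallReadSet(counts={shifted: (2, 0)}, n_leaf=2, n_bud=0)
    assert detect_star_reads(cand, rs) == (True, False)


def test_no_star_reads_anywhere(planted_candidate):
    _, cand = planted_candidate
    rs = SmallReadSet(counts={"A" * 21: (5, 5)}, n_leaf=5, n_bud=5)
    assert detect_star_reads(cand, rs) == (False, False)
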