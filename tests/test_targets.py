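"""Complementarity penalty scoring and target search."""

import numpy as np
import pytest

from mirseed.seqs import revcomp
from mirseed.simulate import simulate_cds_with_sites
from mirseed.targets import (
    ScoringScheme,
    _align_one,
    _pair_class,
    best_hits,
    find_targets,
    score_alignment,
)


def site_for(mirna: str) -> str:
    """Perfectly complementary target site, written 3'->5'."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in mirna)


MIRNA = "ACGTACGTACGTACGTACGTA"


def test_perfect_complement_scores_zero():
    assert score_alignment(MIRNA, site_for(MIRNA), ScoringScheme()) == 0.0


def test_wobble_outside_region_costs_half():
    site = list(site_for(MIRNA))
    # miRNA position 15 is G (1-based); G:U wobble -> target T
    assert MIRNA[14] == "G"
    site[14] = "T"
    assert score_alignment(MIRNA, "".join(site)) == 0.5


def test_mismatch_in_region_is_doubled():
    site = list(site_for(MIRNA))
    site[4] = "A"  # position 5: A:A mismatch inside positions 2-13
    assert score_alignment(MIRNA, "".join(site)) == 2.0


def test_gap_penalties_and_length_check():
    with pytest.raises(ValueError):
        score_alignment("ACGT", "TGC")
    # deletion of miRNA position 15 (outside region): 2.0
    m = MIRNA[:14] + MIRNA[14] + MIRNA[15:]
    aln_m = MIRNA
    aln_t = site_for(MIRNA)[:14] + "-" + site_for(MIRNA)[15:]
    assert score_alignment(aln_m, aln_t) == 2.0


def test_score_additive_over_independent_edits():
    site = list(site_for(MIRNA))
    site[14] = "T"  # wobble outside: 0.5
    site[0] = "C"  # position 1 mismatch outside region: 1.0
    assert score_alignment(MIRNA, "".join(site)) == 1.5


def test_adding_a_mismatch_never_decreases_score():
    rng = np.random.default_rng(3)
    scheme = ScoringScheme()
    for _ in range(20):
        m = "".join(rng.choice(list("ACGT"), 21))
        site = list(site_for(m))
        base = score_alignment(m, "".join(site), scheme)
        p = int(rng.integers(0, 21))
        site[p] = {"A": "C", "C": "T", "G": "A", "T": "C"}[m[p]]
        assert score_alignment(m, "".join(site), scheme) >= base


def test_engineered_sites_recovered_at_intended_scores():
    mirnas = {
        "m1": "GCTTAAAAGCCATGGAATCTT",
        "m2": "ACGCAGCCCCCTCGTACGAGG",
        "m3": "GTCTTTCATTCGATTCTATTT",
        "m4": "GATGATACTTACTGACGACCC",
    }
    scores = [0.0, 0.5, 2.5, 4.5]
    cds, truth = simulate_cds_with_sites(mirnas, scores, seed=11)
    hits = find_targets(mirnas, cds, ScoringScheme())
    by_pair = {(h.mirna_id, h.cds_id): h.score for h in hits}
    for row in truth.itertuples():
        if row.intended_score < 4.0:
            assert by_pair[(row.mirna, row.cds)] == pytest.approx(row.intended_score)
        else:
            assert (row.mirna, row.cds) not in by_pair  # strict "<" cutoff


def test_intended_zero_site_is_exact_reverse_complement():
    mirnas = {"m1": "GCTTAAAAGCCATGGAATCTT"}
    cds, truth = simulate_cds_with_sites(mirnas, [0.0], seed=2)
    row = truth.iloc[0]
    site = cds[row.cds][row.site_start : row.site_end]
    assert site == revcomp(mirnas["m1"])


def test_dp_matches_exhaustive_enumeration_small():
    scheme = ScoringScheme()

    def subcost(mb, tb, pos):
        cls = _pair_class(mb, tb)
        pen = 0.0 if cls == "wc" else (0.5 if cls == "wobble" else 1.0)
        return pen * scheme.factor(pos)

    def brute(mirna, cds):
        rev = cds[::-1]
        m, n = len(mirna), len(rev)
        best = np.inf
        for j0 in range(n - m + 1):  # no gap
            best = min(
                best, sum(subcost(mirna[i], rev[j0 + i], i + 1) for i in range(m))
            )
        for d in range(1, m + 1):  # one miRNA base deleted
            for j0 in range(n - (m - 1) + 1):
                s, j = scheme.gap * scheme.factor(d), j0
                for i in range(1, m + 1):
                    if i == d:
                        continue
                    s += subcost(mirna[i - 1], rev[j], i)
                    j += 1
                best = min(best, s)
        for i0 in range(1, m):  # one target base inserted after miRNA pos i0
            for j0 in range(n - (m + 1) + 1):
                s, j = scheme.gap * scheme.factor(min(i0 + 1, m)), j0
                for i in range(1, m + 1):
                    s += subcost(mirna[i - 1], rev[j], i)
                    j += 1
                    if i == i0:
                        j += 1
                best = min(best, s)
        return best

    rng = np.random.default_rng(17)
    for _ in range(25):
        mirna = "".join(rng.choice(list("ACGT"), 21))
        cds = "".join(rng.choice(list("ACGT"), 30))
        res = _align_one(mirna, cds, scheme)
        assert res[0] == pytest.approx(brute(mirna, cds))
        # the reported alignment rescales to the reported score
        assert score_alignment(res[3], res[4], scheme) == pytest.approx(res[0])


def test_best_hits_selects_each_mirnas_minimum():
    mirnas = {"m1": "GCTTAAAAGCCATGGAATCTT"}
    cds, _ = simulate_cds_with_sites({"a": mirnas["m1"], "b": mirnas["m1"]}, [1.0, 0.5], seed=3)
    hits = find_targets(mirnas, cds, ScoringScheme())
    assert len(hits) == 2
    assert [h.score for h in best_hits(hits)] == [0.5]


def test_unreachable_score_rejected():
    with pytest.raises(ValueError):
        simulate_cds_with_sites({"m": "GCTTAAAAGCCATGGAATCTT"}, [0.25], seed=0)
    with pytest.raises(ValueError):
        # 21-nt miRNA: 9 outside positions (1 + 2.5 doubled... ) cannot host 40
        simulate_cds_with_sites({"m": "GCTTAAAAGCCATGGAATCTT"}, [40.0], seed=0)
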