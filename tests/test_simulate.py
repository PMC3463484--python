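"""Synthetic-data generator: determinism, planted structure, count laws."""

import numpy as np
import pytest

from mirseed.fold import fold_builtin
from mirseed.patmatch import find_all
from mirseed.preprocess import collapse_and_count
from mirseed.seqs import revcomp
from mirseed.simulate import (
    PlacementError,
    SimConfig,
    build_hairpin_locus,
    simulate_libraries,
)


def test_hairpin_locus_mature_mostly_paired_by_folder():
    hp = build_hairpin_locus("GCTTAAAAGCCATGGAATCTT", seed=1)
    f = fold_builtin(hp.precursor)
    paired = sum(
        1
        for i in range(hp.mature_offset, hp.mature_offset + hp.mature_length)
        if f.pair_table[i] >= 0
    )
    assert paired >= 17


def test_hairpin_locus_deterministic_and_seed_sensitive():
    m = "ACGTTGCAGCGTACAAGGCTA"
    a = build_hairpin_locus(m, seed=1)
    b = build_hairpin_locus(m, seed=1)
    c = build_hairpin_locus(m, seed=2)
    assert a == b
    assert c.loop != a.loop
    assert a.precursor[a.mature_offset : a.mature_offset + 21] == m
    assert c.precursor[c.mature_offset : c.mature_offset + 21] == m


def test_hairpin_locus_length_validation():
    with pytest.raises(ValueError):
        build_hairpin_locus("ACGT" * 4, seed=0)  # 16 nt
    with pytest.raises(ValueError):
        build_hairpin_locus("A" * 25, seed=0)


@pytest.fixture(scope="module")
def sim():
    return simulate_libraries(SimConfig(seed=7))


def test_simulation_is_deterministic(sim):
    again = simulate_libraries(SimConfig(seed=7))
    assert again.reads_leaf == sim.reads_leaf
    assert again.reads_bud == sim.reads_bud
    assert again.genome == sim.genome
    assert [vars(t) for t in again.truth] == [vars(t) for t in sim.truth]


def test_truth_coordinates_slice_to_stored_sequences(sim):
    for t in sim.truth:
        seg = sim.genome[t.chrom][t.start : t.end]
        if t.strand == "-":
            seg = revcomp(seg)
        assert seg == t.mature_seq, t.locus_id
        if t.cls != "repeat":
            star = sim.genome[t.chrom][t.star_start : t.star_end]
            if t.strand == "-":
                star = revcomp(star)
            assert star == t.star_seq, t.locus_id


def test_repeat_loci_occur_more_than_ten_times(sim):
    for t in sim.truth:
        if t.cls != "repeat":
            continue
        n = sum(
            len(find_all(t.mature_seq, text, k=0)) for text in sim.genome.values()
        )
        assert n > 10, t.locus_id


def test_conserved_matures_within_two_subs_of_reference(sim):
    fams = {rid.split("_")[0]: seq for rid, seq in sim.reference.items()}
    for t in sim.truth:
        if t.cls != "conserved":
            continue
        ref = fams[t.family]
        d = sum(a != b for a, b in zip(t.mature_seq, ref))
        assert d <= 2 and len(t.mature_seq) == len(ref)


def test_read_length_histogram_is_bimodal(sim):
    lengths = np.array([len(r) for r in sim.reads_leaf + sim.reads_bud])
    counts = {l: (lengths == l).sum() for l in range(18, 25)}
    assert counts[21] > counts[20] and counts[21] > counts[22]
    assert counts[24] > counts[23]


def test_all_reads_map_to_loci_without_background():
    cfg = SimConfig(
        seed=1,
        n_conserved_loci=3,
        n_novel_loci=2,
        n_repeat_loci=0,
        background_read_fraction=0.0,
        contaminant_read_fraction=0.0,
        lib_sizes=(800, 800),
        genome_length=24_000,
    )
    s = simulate_libraries(cfg)
    valid = set()
    for t in s.truth:
        g = s.genome[t.chrom]
        dom = g[t.start : t.end]
        plus = g[t.start : t.end + 1]
        star = g[t.star_start : t.star_end]
        if t.strand == "-":
            dom, plus, star = revcomp(dom), revcomp(g[t.start - 1 : t.end]), revcomp(star)
        valid |= {dom, dom[:-1], plus, star}
    for r in s.reads_leaf + s.reads_bud:
        assert r in valid


def test_unit_fold_change_gives_balanced_counts():
    cfg = SimConfig(seed=5, de_up_loci=0, de_down_loci=0, lib_sizes=(20_000, 20_000))
    s = simulate_libraries(cfg)
    for t in s.truth:
        if t.cls == "repeat" or t.count_leaf + t.count_bud < 200:
            continue
        # equal sampling: bud fraction ~ Binomial(n, 1/2); allow 5 sigma
        n = t.count_leaf + t.count_bud
        assert abs(t.count_bud - n / 2) < 5 * np.sqrt(n / 4), t.locus_id


def test_eightfold_locus_count_ratio_in_expected_range(sim):
    seen = 0
    for t in sim.truth:
        if t.fold_change == 8.0 and t.count_bud >= 200:
            seen += 1
            assert 4.0 <= t.count_bud / max(t.count_leaf, 1) <= 16.0, t.locus_id
    assert seen >= 1


def test_infeasible_placement_raises():
    with pytest.raises(PlacementError):
        simulate_libraries(
            SimConfig(seed=0, genome_length=4000, n_chromosomes=8, n_conserved_loci=30)
        )
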