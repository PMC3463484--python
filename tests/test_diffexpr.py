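"""Binomial-model differential expression: MA test, Fisher, LRT, calls."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from mirseed.diffexpr import (
    bh_adjust,
    call_de,
    conditional_null_moments,
    fisher_test,
    lr_test,
    ma_test,
)


def test_symmetric_counts_give_null_result():
    r = ma_test([100], [100], 10_000, 10_000)
    assert r.M[0] == 0.0
    assert r.E_M_given_A[0] == pytest.approx(0.0)
    assert r.z[0] == pytest.approx(0.0)
    assert r.p[0] == pytest.approx(1.0)


def test_eightfold_change_is_far_from_null():
    r = ma_test([800], [100], 10_000, 10_000)
    assert abs(r.z[0]) >= 3.0
    assert r.direction[0] == "up-in-leaf"


def test_zero_zero_counts_untestable():
    r = ma_test([0], [0], 1000, 1000)
    assert r.p[0] == 1.0
    assert r.direction[0] == "untestable"


def test_conditional_moments_match_numeric_double_integral():
    """Closed-form E(M|A), Var(M|A) vs direct integration of the
    conditional density of M given A under the delta-method normals."""
    rng = np.random.default_rng(1)
    ln2sq = math.log(2.0) ** 2
    checked = 0
    while checked < 8:
        n1, n2 = rng.integers(10**5, 10**6, 2).astype(float)
        pv = 10 ** rng.uniform(-4.5, -3)
        c1 = float(rng.binomial(int(n1), pv))
        c2 = float(rng.binomial(int(n2), pv))
        if c1 == 0 or c2 == 0:
            continue
        checked += 1
        m, a, em, vm = conditional_null_moments(np.array([c1]), np.array([c2]), n1, n2)
        phat = (c1 + c2) / (n1 + n2)
        mux, muy = np.log2(n1 * phat), np.log2(n2 * phat)
        sx = math.sqrt((1 - phat) / (n1 * phat * ln2sq))
        sy = math.sqrt((1 - phat) / (n2 * phat * ln2sq))
        A = float(a[0])

        def dens(mm):
            return stats.norm.pdf(A + mm / 2, mux, sx) * stats.norm.pdf(A - mm / 2, muy, sy)

        z0 = integrate.quad(dens, -20, 20, limit=200)[0]
        z1 = integrate.quad(lambda mm: mm * dens(mm), -20, 20, limit=200)[0]
        z2 = integrate.quad(lambda mm: mm * mm * dens(mm), -20, 20, limit=200)[0]
        assert em[0] == pytest.approx(z1 / z0, abs=1e-7)
        assert vm[0] == pytest.approx(z2 / z0 - (z1 / z0) ** 2, rel=1e-6)


def test_null_calibration_within_band():
    """Type-I error under the binomial null stays near nominal."""
    rng = np.random.default_rng(42)
    n = 2_000_000
    p = 10 ** rng.uniform(-5, -3, 2000)
    c1, c2 = rng.binomial(n, p), rng.binomial(n, p)
    res = ma_test(c1, c2, n, n)
    for alpha, lo, hi in [(0.05, 0.025, 0.10), (0.01, 0.005, 0.02)]:
        assert lo <= (res.p < alpha).mean() <= hi


def test_fisher_balanced_table_is_null():
    assert fisher_test([5], [5], 100, 100).p[0] == pytest.approx(1.0)


def test_fisher_row_swap_symmetry():
    p1 = fisher_test([8], [1], 10, 10).p[0]
    p2 = fisher_test([1], [8], 10, 10).p[0]
    assert p1 == pytest.approx(p2)


def test_fisher_matches_exhaustive_hypergeometric_sum():
    def brute(c1, n1, c2, n2):
        k = c1 + c2
        p_obs = math.comb(n1, c1) * math.comb(n2, c2)
        tot = 0
        for x in range(max(0, k - n2), min(n1, k) + 1):
            w = math.comb(n1, x) * math.comb(n2, k - x)
            if w <= p_obs:  # exact integer comparison
                tot += w
        return tot / math.comb(n1 + n2, k)

    assert fisher_test([8], [1], 10, 10).p[0] == pytest.approx(brute(8, 10, 1, 10))
    rng = np.random.default_rng(0)
    for _ in range(40):
        n1, n2 = rng.integers(3, 31, 2)
        c1, c2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        assert fisher_test([c1], [c2], int(n1), int(n2)).p[0] == pytest.approx(
            brute(int(c1), int(n1), int(c2), int(n2)), abs=1e-12
        )


def test_lrt_equal_proportions_give_zero():
    r = lr_test([10], [20], 100, 200)
    assert r.g2[0] == pytest.approx(0.0)
    assert r.p[0] == pytest.approx(1.0)


def test_lrt_matches_numeric_likelihood_maximization():
    rng = np.random.default_rng(8)
    for _ in range(30):
        n1, n2 = rng.integers(50, 500, 2)
        c1, c2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        r = lr_test([c1], [c2], int(n1), int(n2))

        def nll(p):
            return -(xlogy(c1, p) + xlogy(n1 - c1, 1 - p) + xlogy(c2, p) + xlogy(n2 - c2, 1 - p))

        opt = minimize_scalar(nll, bounds=(1e-12, 1 - 1e-12), method="bounded")
        ll1 = (
            xlogy(c1, c1 / n1)
            + xlogy(n1 - c1, 1 - c1 / n1)
            + xlogy(c2, c2 / n2)
            + xlogy(n2 - c2, 1 - c2 / n2)
        )
        assert r.g2[0] == pytest.approx(2 * (ll1 + opt.fun), abs=1e-5)


def test_lrt_handles_boundary_counts():
    r = lr_test([0, 100], [5, 0], 100, 100)
    assert np.isfinite(r.g2).all()
    assert ((r.p >= 0) & (r.p <= 1)).all()


def test_methods_agree_in_direction():
    c1 = [10, 500, 3, 120]
    c2 = [100, 50, 3, 119]
    n1 = n2 = 10_000
    frames = [ma_test(c1, c2, n1, n2), fisher_test(c1, c2, n1, n2), lr_test(c1, c2, n1, n2)]
    for a, b in zip(frames, frames[1:]):
        assert list(a.direction) == list(b.direction)


def test_deeper_sequencing_increases_power():
    z1 = abs(ma_test([40], [80], 10_000, 10_000).z[0])
    z2 = abs(ma_test([80], [160], 20_000, 20_000).z[0])
    assert z2 > z1


def test_bh_matches_hand_computed_toy():
    p = np.array([0.001, 0.01, 0.02, 0.8, 1.0])
    # step-up by hand: p*(n/rank) = .005, .025, .0333.., 1.0, 1.0
    expected = [0.005, 0.025, 0.02 * 5 / 3, 1.0, 1.0]
    assert bh_adjust(p) == pytest.approx(expected)


def test_call_de_no_calls_when_all_null():
    res = ma_test([10, 20], [10, 20], 1000, 1000)
    up_bud, up_leaf, out = call_de(res)
    assert up_bud == [] and up_leaf == []
    assert (out.q >= out.p).all()


def test_call_de_empty_input():
    import pandas as pd

    up_bud, up_leaf, out = call_de(pd.DataFrame(columns=["p", "direction"]))
    assert up_bud == [] and up_leaf == [] and len(out) == 0
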