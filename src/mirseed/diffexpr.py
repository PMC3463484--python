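"""Two-library differential expression under the binomial sampling model.

With one sequencing library per condition, the read count of a feature is
modelled as binomial in the library total.  Three tests are provided:

* ``ma_test`` — the MA-plot conditional-normal test: with X = log2 C1 and
  Y = log2 C2, M = X - Y and A = (X + Y)/2, the delta method gives the
  null moments of X and Y under a pooled sampling proportion, and
  conditioning the bivariate normal (M, A) on the observed A yields
  E(M|A) and Var(M|A); the statistic is z = (M - E(M|A)) / sqrt(Var(M|A)).
* ``fisher_test`` — two-sided exact test on the 2x2 table
  [[C1, n1-C1], [C2, n2-C2]].
* ``lr_test`` — binomial likelihood-ratio test (G²) against chi² (1 df).

Calls are made after Benjamini-Hochberg adjustment; direction comes from
the sign of M after centering by the library-size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

_LN2_SQ = np.log(2.0) ** 2


def _as_arrays(c1, c2) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.atleast_1d(np.asarray(c1, dtype=float))
    c2 = np.atleast_1d(np.asarray(c2, dtype=float))
    if c1.shape != c2.shape:
        raise ValueError("count vectors must have equal length")
    return c1, c2


def conditional_null_moments(
    c1: np.ndarray, c2: np.ndarray, n1: float, n2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(M, A, E(M|A), Var(M|A)) under the pooled binomial null.

    Zero counts are floored to 1 inside the log2 transform only; the
    pooled proportion uses the raw counts.
    """
    x = np.log2(np.maximum(c1, 1.0))
    y = np.log2(np.maximum(c2, 1.0))
    m = x - y
    a = (x + y) / 2.0
    phat = (c1 + c2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_x = np.log2(n1 * phat)
        mu_y = np.log2(n2 * phat)
        var_x = (1.0 - phat) / (n1 * phat * _LN2_SQ)
        var_y = (1.0 - phat) / (n2 * phat * _LN2_SQ)
        mu_m = mu_x - mu_y
        mu_a = (mu_x + mu_y) / 2.0
        var_sum = var_x + var_y
        e_m_a = mu_m + 2.0 * (var_x - var_y) / var_sum * (a - mu_a)
        var_m_a = 4.0 * var_x * var_y / var_sum
    return m, a, e_m_a, var_m_a


def ma_test(c1, c2, n1: float, n2: float) -> pd.DataFrame:
    """MA-plot conditional-normal test; one row per feature.

    Features with C1 = C2 = 0 are untestable and get p = 1.
    """
    c1, c2 = _as_arrays(c1, c2)
    m, a, e_m_a, var_m_a = conditional_null_moments(c1, c2, n1, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - e_m_a) / np.sqrt(var_m_a)
    untestable = (c1 + c2) == 0
    z = np.where(untestable, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(untestable, 1.0, p)
    return _result_frame(c1, c2, n1, n2, m, a, z, p, "ma", e_m_a, var_m_a, untestable)


def fisher_test(c1, c2, n1: float, n2: float) -> pd.DataFrame:
    """Two-sided Fisher exact test on [[C1, n1-C1], [C2, n2-C2]] per feature."""
    c1, c2 = _as_arrays(c1, c2)
    m, a, e_m_a, var_m_a = conditional_null_moments(c1, c2, n1, n2)
    p = np.empty_like(c1)
    for i, (a1, a2) in enumerate(zip(c1, c2)):
        table = [[int(a1), int(n1 - a1)], [int(a2), int(n2 - a2)]]
        p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    z = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0)) * np.sign(m)
    return _result_frame(c1, c2, n1, n2, m, a, z, p, "fisher", e_m_a, var_m_a, (c1 + c2) == 0)


def lr_test(c1, c2, n1: float, n2: float) -> pd.DataFrame:
    """Binomial likelihood-ratio (G²) test per feature, chi² with 1 df.

    Boundary maximum-likelihood estimates follow the 0*log(0) = 0
    convention via ``xlogy``.
    """
    c1, c2 = _as_arrays(c1, c2)

    def loglik(c, n, p):
        return xlogy(c, p) + xlogy(n - c, 1.0 - p)

    p1 = c1 / n1
    p2 = c2 / n2
    pp = (c1 + c2) / (n1 + n2)
    g2 = 2.0 * (
        loglik(c1, n1, p1) + loglik(c2, n2, p2) - loglik(c1, n1, pp) - loglik(c2, n2, pp)
    )
    g2 = np.maximum(g2, 0.0)
    p = stats.chi2.sf(g2, df=1)
    m, a, e_m_a, var_m_a = conditional_null_moments(c1, c2, n1, n2)
    z = np.sqrt(g2) * np.sign(m - np.log2(n1 / n2))
    out = _result_frame(c1, c2, n1, n2, m, a, z, p, "lrt", e_m_a, var_m_a, (c1 + c2) == 0)
    out["g2"] = g2
    return out


def _result_frame(c1, c2, n1, n2, m, a, z, p, method, e_m_a, var_m_a, untestable):
    centered = m - np.log2(n1 / n2)
    direction = np.where(centered < 0, "up-in-bud", "up-in-leaf")
    direction = np.where(untestable, "untestable", direction)
    return pd.DataFrame(
        {
            "count_leaf": c1.astype(int),
            "count_bud": c2.astype(int),
            "M": m,
            "A": a,
            "E_M_given_A": e_m_a,
            "Var_M_given_A": var_m_a,
            "z": z,
            "p": np.clip(p, 0.0, 1.0),
            "direction": direction,
            "method": method,
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_de(
    results: pd.DataFrame, alpha: float = 0.05, adjustment: str = "bh"
) -> tuple[list, list, pd.DataFrame]:
    """Significance calls after multiple-testing adjustment.

    Returns (up_in_bud indices, up_in_leaf indices, results with a ``q``
    column).  ``adjustment`` is 'bh' (default) or 'none'.
    """
    out = results.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        return [], [], out
    if adjustment == "bh":
        out["q"] = bh_adjust(out["p"].to_numpy())
    elif adjustment == "none":
        out["q"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    sig = out["q"] < alpha
    up_bud = out.index[sig & (out["direction"] == "up-in-bud")].tolist()
    up_leaf = out.index[sig & (out["direction"] == "up-in-leaf")].tolist()
    return up_bud, up_leaf, out
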