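"""Nonparametric statistics used to compare conditions and cohorts.

Friedman tests for a perturbation effect across blocks, post-hoc paired
Wilcoxon signed-rank tests with the Hommel family-wise adjustment, and
a two-sided F-test of variance equality between cohorts (the test that
discriminates the delay-compensation strategies at the highest delay
level).

The Wilcoxon Z uses the plain normal approximation with mid-ranks and
zero-difference removal and no continuity correction; at n = 20 with
all differences one-signed this gives W = 210, Z = 3.9199.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "friedman",
    "wilcoxon_signed_rank",
    "hommel_adjust",
    "variance_f_test",
    "pairwise_wilcoxon",
    "cohort_summary",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-values."""

    name: str
    statistic: float
    df: tuple
    p: float
    z: float | None = None
    adjusted_p: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def friedman(matrix) -> TestResult:
    """Friedman chi-square over a participants x conditions matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and columns")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    if np.all(np.ptp(m, axis=1) == 0):
        # every participant ties across all conditions: no effect
        return TestResult("friedman_chi2", 0.0, (m.shape[1] - 1,), 1.0)
    stat, p = scipy.stats.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return TestResult("friedman_chi2", float(stat), (m.shape[1] - 1,), float(p))


def wilcoxon_signed_rank(a, b, label: str = "") -> TestResult:
    """Paired signed-rank test; W is the rank sum of pairs with b > a.

    Zero differences are removed, ties receive mid-ranks, and the
    two-sided p comes from the normal approximation
    ``Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie_term)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0.0]
    n = len(d)
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))
    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise ValueError("degenerate variance (all differences tied at zero)")
    z = (w_pos - mean_w) / np.sqrt(var_w)
    p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return TestResult("wilcoxon_W", w_pos, (n,), min(p, 1.0), z=float(z),
                      label=label)


def hommel_adjust(p_values) -> np.ndarray:
    """Hommel step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="hommel")[1]


def variance_f_test(a, b, label: str = "") -> TestResult:
    """Two-sided F-test of variance equality, ``F = var(a) / var(b)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    if vb == 0:
        return TestResult("variance_F", np.inf, (dfa, dfb), 0.0,
                          label=label or "degenerate: zero denominator variance")
    f = va / vb
    dist = scipy.stats.f(dfa, dfb)
    p = float(2.0 * min(dist.cdf(f), dist.sf(f)))
    return TestResult("variance_F", float(f), (dfa, dfb), min(p, 1.0),
                      label=label)


def pairwise_wilcoxon(matrix, labels=None) -> pd.DataFrame:
    """All pairwise signed-rank tests across conditions, Hommel-adjusted.

    ``matrix`` is participants x conditions; returns one row per pair
    with raw and adjusted p-values.
    """
    m = np.asarray(matrix, dtype=float)
    k = m.shape[1]
    labels = labels if labels is not None else list(range(k))
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            r = wilcoxon_signed_rank(m[:, i], m[:, j],
                                     label=f"{labels[i]} vs {labels[j]}")
            results.append(r)
    adj = hommel_adjust([r.p for r in results])
    return pd.DataFrame({
        "comparison": [r.label for r in results],
        "W": [r.statistic for r in results],
        "Z": [r.z for r in results],
        "n": [r.df[0] for r in results],
        "p": [r.p for r in results],
        "p_adjusted": adj,
    })


def cohort_summary(df: pd.DataFrame, metric: str = "rmse_deg") -> pd.DataFrame:
    """Median / IQR / variance of a cohort metric per strategy and block."""
    g = df.groupby(["strategy", "block", "level"])[metric]
    out = g.agg(median="median",
                q1=lambda x: np.percentile(x, 25),
                q3=lambda x: np.percentile(x, 75),
                variance=lambda x: np.var(x, ddof=1),
                mean="mean").reset_index()
    return out
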