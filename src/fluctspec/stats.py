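"""Spectrum-comparison statistics: Fisher exact, chi-square, proportion CIs.

Thin, validated wrappers over scipy/statsmodels with the conventions used
for mutation-spectrum comparisons: two-sided Fisher by the probability-mass
method, Wilson score intervals for proportions, and per-class 2x2 collapses
with Benjamini-Hochberg adjustment when two whole spectra are compared
(raw p-values are always reported alongside the adjusted ones).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "fisher_exact",
    "chi_square",
    "wilson_ci",
    "clopper_pearson_ci",
    "compare_spectra",
]


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0 and t.sum() == 0:
        raise ValueError("empty table")
    return t


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value (probability-mass method).

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    t = _check_2x2(table)
    if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
        return 1.0  # a degenerate margin carries no information
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square for a 2 x k table; returns (statistic, p).

    df = k - 1; no continuity correction.  Warns when any expected cell is
    below 5, where the asymptotic p-value is unreliable.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected counts are undefined")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "expected cell count below 5; chi-square p-value is approximate",
            stacklevel=2,
        )
    return float(stat), float(p)


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    if k == 0:
        lo = 0.0  # the Wilson lower bound is exactly 0 at k = 0
    if k == n:
        hi = 1.0
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval, available behind a flag."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def _odds_ratio(a, b, c, d) -> float:
    if 0 in (a, b, c, d):  # Haldane-Anscombe correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def compare_spectra(counts_a, counts_b) -> pd.DataFrame:
    """Per-class comparison of two spectra (class vs rest, Fisher exact).

    ``counts_a`` and ``counts_b`` map class label -> count over the same
    class set.  Each class is collapsed to a 2x2 table against the rest;
    the per-class p-values get a Benjamini-Hochberg adjustment (column q).
    """
    a = pd.Series(counts_a, dtype=int)
    b = pd.Series(counts_b, dtype=int)
    if set(a.index) != set(b.index):
        raise ValueError("spectra must share the same class set")
    b = b.reindex(a.index)
    n_a, n_b = int(a.sum()), int(b.sum())
    rows = []
    for label in a.index:
        ka, kb = int(a[label]), int(b[label])
        table = [[ka, n_a - ka], [kb, n_b - kb]]
        rows.append(
            {
                "class": label,
                "k_a": ka,
                "n_a": n_a,
                "k_b": kb,
                "n_b": n_b,
                "odds_ratio": _odds_ratio(ka, n_a - ka, kb, n_b - kb),
                "p": fisher_exact(table),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
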