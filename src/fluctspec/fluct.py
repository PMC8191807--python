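"""Fluctuation-assay mutation-rate estimation (Lea-Coulson method of the median).

A fluctuation assay grows C parallel cultures without selection and plates
each on selective medium; the distribution of selected-colony counts
r_1..r_C estimates the per-locus per-division mutation rate.  The method of
the median solves the Lea-Coulson relation

    r_median / m - ln(m) = 1.24

for m, the expected number of mutations per culture, and converts to the
rate mu = m / N where N is the final viable cell count per culture.  When
the median is zero the P0 method m = -ln(P0) applies instead.

The module follows the statsmodels shape: :class:`FluctuationModel` holds
the data, ``fit()`` returns a :class:`FluctuationResults` with the estimate,
a bootstrap confidence interval, and a ``summary()`` table.  The total rate
is partitioned over mutation classes via sequenced-mutant counts
(:func:`class_rates`): class rate = mu * k / n, with the zero-count rule
that an unobserved class gets the upper bound mu / n (the rate it would
have had with a single event), flagged "<".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .stats import wilson_ci

__all__ = [
    "FluctuationAssay",
    "FluctuationModel",
    "FluctuationResults",
    "ClassRateTable",
    "ClassRateRow",
    "lc_median_m",
    "p0_m",
    "rate_from_m",
    "class_rates",
    "fold_change",
    "fraction_of_total",
    "ma_rate",
    "sig3",
    "LEA_COULSON_CONSTANT",
]

LEA_COULSON_CONSTANT = 1.24


def sig3(x: float) -> float:
    """Round to 3 significant figures (the rate-table display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.3g}")


@dataclass
class FluctuationAssay:
    """Per-culture selected-colony counts plus the viable-cell count.

    ``cells_per_culture`` may be a single pooled value or one per culture;
    pooled assays use the median across cultures.
    """

    culture_counts: list[int]
    cells_per_culture: float | list[float]
    label: str = ""

    def __post_init__(self):
        if len(self.culture_counts) < 2:
            raise ValueError("need at least 2 cultures")
        if any(c < 0 or int(c) != c for c in self.culture_counts):
            raise ValueError("culture counts must be non-negative integers")
        if self.n_cells <= 0:
            raise ValueError("viable cell count must be positive")

    @property
    def n_cells(self) -> float:
        if isinstance(self.cells_per_culture, (int, float)):
            return float(self.cells_per_culture)
        return float(np.median(self.cells_per_culture))


def lc_median_m(culture_counts) -> float:
    """Expected mutations per culture by the method of the median.

    Solves r_median/m - ln(m) = 1.24 by bracketed root finding (the left side
    is strictly decreasing in m, so the root is unique).  Requires a median
    of at least 1; a zero median has no information for this estimator and
    the caller is directed to the P0 method.
    """
    counts = np.asarray(list(culture_counts), dtype=float)
    if counts.size == 0 or np.all(counts == 0):
        raise ValueError("all culture counts are zero: no mutants observed")
    r_med = float(np.median(counts))
    if r_med < 1:
        raise ValueError(
            f"median mutant count {r_med} < 1; use the P0 method (p0_m) instead"
        )

    def f(m):
        return r_med / m - math.log(m) - LEA_COULSON_CONSTANT

    lo = 1e-9
    hi = max(r_med, 2.0)
    while f(hi) > 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-12))


def p0_m(culture_counts) -> float:
    """P0 estimate: m = -ln(fraction of cultures with zero mutants)."""
    counts = np.asarray(list(culture_counts), dtype=float)
    n_zero = int(np.sum(counts == 0))
    if n_zero == 0:
        raise ValueError("no zero-count cultures: the P0 method does not apply")
    p0 = n_zero / counts.size
    if n_zero == counts.size:
        import warnings

        warnings.warn("all cultures have zero mutants; m = 0", stacklevel=2)
    return -math.log(p0) if p0 < 1 else 0.0


def rate_from_m(m: float, n_cells: float) -> float:
    """Mutation rate per locus per division, mu = m / N."""
    if n_cells <= 0:
        raise ValueError("N must be positive")
    return m / n_cells


def fold_change(rate_test: float, rate_baseline: float, is_bound: bool = False):
    """Raw rate ratio; display layer rounds to the nearest integer.

    With ``is_bound`` the baseline is an upper bound, so the returned ratio
    is a lower bound on the true fold change.
    """
    if rate_baseline <= 0:
        raise ValueError("baseline rate must be positive (or pass its bound)")
    return rate_test / rate_baseline


def fraction_of_total(class_rate: float, total_rate: float) -> float:
    """Class share of the total rate, as a percentage (display rounds to int)."""
    if total_rate <= 0:
        raise ValueError("total rate must be positive")
    return 100.0 * class_rate / total_rate


def ma_rate(
    mutation_count: int, genome_bp: float, divisions_per_line: float, n_lines: int
) -> float:
    """Mutation-accumulation rate per bp per cell division.

    count / (genome size x divisions per line x number of lines).
    """
    denom = genome_bp * divisions_per_line * n_lines
    if denom <= 0:
        raise ValueError("genome_bp, divisions_per_line and n_lines must be positive")
    return mutation_count / denom


@dataclass(frozen=True)
class ClassRateRow:
    label: str
    k: int
    rate: float  # exact value, mutations per locus per division
    is_bound: bool  # True when k == 0 and rate is the single-event upper bound
    ci95: tuple[float, float] | None = None

    def display(self, scale: float = 1e-9) -> str:
        val = sig3(self.rate / scale)
        return f"<{val:g}" if self.is_bound else f"{val:g}"


@dataclass
class ClassRateTable:
    """Per-class partition of a total mutation rate.

    Class rate = total * k/n from the sequenced-mutant counts; zero-count
    classes carry the single-event upper bound total/n.  Before any display
    rounding the observed-class rates sum exactly to the total.
    """

    total_rate: float
    n: int
    rows: list[ClassRateRow]

    def __post_init__(self):
        k_sum = sum(r.k for r in self.rows)
        if k_sum != self.n:
            raise ValueError(f"class counts sum to {k_sum}, expected n = {self.n}")

    def rate_of(self, label: str) -> ClassRateRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_frame(self, scale: float = 1e-9) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [r.label for r in self.rows],
                "k": [r.k for r in self.rows],
                "n": self.n,
                "rate": [r.rate for r in self.rows],
                "bound": ["<" if r.is_bound else "" for r in self.rows],
                "display": [r.display(scale) for r in self.rows],
            }
        )


def class_rates(
    total_rate: float,
    class_counts: dict[str, int],
    n: int,
    total_ci: tuple[float, float] | None = None,
    ci_level: float = 0.95,
) -> ClassRateTable:
    """Partition a total rate over mutation classes.

    ``class_counts`` maps class label -> number among the n sequenced
    mutants.  Per-class CIs, when a total-rate CI is supplied, are a
    composite: the total-rate CI bounds scaled by the Wilson interval on
    k/n (documented stand-in; tagged in the output).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k_sum = sum(class_counts.values())
    if k_sum != n:
        raise ValueError(f"class counts sum to {k_sum}, expected n = {n}")
    rows = []
    for label, k in class_counts.items():
        if k < 0:
            raise ValueError("counts must be non-negative")
        if k == 0:
            rate = total_rate / n  # single-event upper bound
            bound = True
        else:
            rate = total_rate * k / n
            bound = False
        ci = None
        if total_ci is not None:
            w_lo, w_hi = wilson_ci(k, n, level=ci_level)
            ci = (total_ci[0] * w_lo, total_ci[1] * w_hi)
        rows.append(ClassRateRow(label=label, k=k, rate=rate, is_bound=bound, ci95=ci))
    return ClassRateTable(total_rate=total_rate, n=n, rows=rows)


class FluctuationModel:
    """Mutation-rate model for one fluctuation assay.

    Parameters
    ----------
    culture_counts : sequence of int
        Selected-colony counts, one per culture.
    cells_per_culture : float or sequence of float
        Final viable cell count N (pooled value or per culture; pooled
        assays use the median).
    label : str
        Strain / gene / temperature metadata carried into the summary.
    """

    def __init__(self, culture_counts, cells_per_culture, label: str = ""):
        self.assay = FluctuationAssay(
            culture_counts=list(culture_counts),
            cells_per_culture=cells_per_culture,
            label=label,
        )

    @classmethod
    def from_assay(cls, assay: FluctuationAssay) -> "FluctuationModel":
        model = cls.__new__(cls)
        model.assay = assay
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        count_col: str = "selected_count",
        cells_col: str = "viable_count",
        label: str = "",
    ) -> "FluctuationModel":
        return cls(
            df[count_col].astype(int).tolist(),
            df[cells_col].astype(float).tolist(),
            label=label,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, assay_id: str | None = None) -> "FluctuationModel":
        """Read the assay TSV (assay_id, culture_id, selected_count, viable_count)."""
        tab = pd.read_csv(path, sep="\t", comment="#")
        if assay_id is not None:
            tab = tab[tab["assay_id"] == assay_id]
            if tab.empty:
                raise ValueError(f"{path}: no rows for assay_id {assay_id!r}")
        return cls.from_dataframe(tab, label=str(assay_id or ""))

    def fit(
        self,
        method: str = "auto",
        n_boot: int = 10_000,
        seed: int | None = None,
        ci_level: float = 0.95,
    ) -> "FluctuationResults":
        """Estimate m and mu.

        method "auto" uses the median method when the median count is >= 1
        and falls back to P0 otherwise.  The CI is a nonparametric bootstrap
        over cultures (percentile interval, seeded); n_boot = 0 skips it.
        """
        counts = np.asarray(self.assay.culture_counts, dtype=float)
        used = method
        if method == "auto":
            used = "lc_median" if float(np.median(counts)) >= 1 else "p0"
        if used == "lc_median":
            m = lc_median_m(counts)
        elif used == "p0":
            m = p0_m(counts)
        else:
            raise ValueError(f"unknown method {method!r}")
        n_cells = self.assay.n_cells
        rate = rate_from_m(m, n_cells)

        ci = None
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, counts.size, size=(n_boot, counts.size))
            samples = counts[idx]
            medians = np.median(samples, axis=1)
            boot_m = np.empty(n_boot)
            # the bootstrap statistic takes few distinct median values;
            # solve the Lea-Coulson relation once per distinct value
            cache: dict[float, float] = {}
            for i, (med, row) in enumerate(zip(medians, samples)):
                if med >= 1:
                    if med not in cache:
                        cache[med] = lc_median_m([med, med])
                    boot_m[i] = cache[med]
                else:
                    nz = float(np.mean(row == 0))
                    boot_m[i] = -math.log(nz) if 0 < nz < 1 else 0.0
            boot_rate = boot_m / n_cells
            alpha = (1 - ci_level) / 2
            ci = (
                float(np.quantile(boot_rate, alpha)),
                float(np.quantile(boot_rate, 1 - alpha)),
            )
            ci = (min(ci[0], rate), max(ci[1], rate))

        return FluctuationResults(
            model=self, m=m, rate=rate, ci95=ci, method=used, n_boot=n_boot, seed=seed
        )


@dataclass
class FluctuationResults:
    """Fit results: m, the rate, its bootstrap CI, and the partition helper."""

    model: FluctuationModel
    m: float
    rate: float
    ci95: tuple[float, float] | None
    method: str
    n_boot: int = 0
    seed: int | None = None

    def partition(self, class_counts: dict[str, int], n: int | None = None) -> ClassRateTable:
        """Per-class rates from sequenced-mutant counts (see :func:`class_rates`)."""
        if n is None:
            n = sum(class_counts.values())
        return class_rates(self.rate, class_counts, n, total_ci=self.ci95)

    def summary(self) -> str:
        assay = self.model.assay
        counts = assay.culture_counts
        lines = [
            "Fluctuation assay rate estimate",
            "=" * 46,
            f"label:            {assay.label or '-'}",
            f"cultures:         {len(counts)}",
            f"median count:     {np.median(counts):g}",
            f"cells/culture N:  {assay.n_cells:.4g}",
            f"method:           {self.method}",
            f"m (mut/culture):  {self.m:.4g}",
            f"rate mu (/div):   {sig3(self.rate):.3g}",
        ]
        if self.ci95 is not None:
            lines.append(
                f"95% CI:           [{sig3(self.ci95[0]):.3g}, {sig3(self.ci95[1]):.3g}]"
                f"  (bootstrap, {self.n_boot} resamples)"
            )
        lines.append("=" * 46)
        return "\n".join(lines)
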