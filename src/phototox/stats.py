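"""Condition-comparison statistics.

Event-time distributions of two conditions are compared with the
two-sided two-sample Kolmogorov–Smirnov test (asymptotic p-value, the
common reporting convention); per-FOV summaries get percentile-bootstrap
confidence intervals for the mean.  Significance stars follow the usual
thresholds: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.  No
multiple-testing correction is applied by default; a Bonferroni factor
can be supplied where a family of comparisons is reported together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "significance_stars", "ks_two_sided", "bootstrap_ci_mean"]


STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ComparisonResult:
    """Two-sample KS outcome with reporting metadata."""

    ks_statistic: float
    p_value: float
    n1: int
    n2: int
    significance_stars: str


def significance_stars(p_value: float) -> str:
    """'*'..'****' per the conventional p-value thresholds, '' otherwise."""
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return ""


def ks_two_sided(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    bonferroni: int = 1,
) -> ComparisonResult:
    """Two-sided two-sample KS test on pooled event times.

    D = sup |ECDF_a - ECDF_b|; the p-value uses the asymptotic two-sample
    law and is optionally Bonferroni-scaled (capped at 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs two non-empty samples")
    result = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    p = min(1.0, float(result.pvalue) * bonferroni)
    return ComparisonResult(
        ks_statistic=float(result.statistic),
        p_value=p,
        n1=a.size,
        n2=b.size,
        significance_stars=significance_stars(p),
    )


def bootstrap_ci_mean(
    values: np.ndarray,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: (mean, lower, upper).

    Deterministic for a fixed seed; constant input yields a zero-width
    interval at that value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lower), float(upper)
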