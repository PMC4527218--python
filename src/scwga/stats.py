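"""Statistical machinery: Mann-Whitney-Wilcoxon, Bonferroni, Pearson.

Thin, validated surface over scipy with the exact/approximate crossover made
explicit: the exact null distribution of U is used whenever both groups have
at most ``exact_limit`` observations and the pooled sample is tie-free;
otherwise a tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"
    alternative: str


def mann_whitney(x, y, alternative: str = "two-sided", exact_limit: int = 20) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p-value set to 1", stacklevel=2)
        return TestResult(x.size * y.size / 2.0, 1.0, "normal-approximation", alternative)
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and x.size <= exact_limit and y.size <= exact_limit
    res = _sps.mannwhitneyu(
        x, y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "exact" if exact else "normal-approximation",
        alternative,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    return float(_sps.pearsonr(x, y).statistic)
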