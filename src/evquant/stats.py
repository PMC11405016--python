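"""The statistical procedures the quantification figures rely on.

Only four operations, implemented once with explicit conventions:

* Student's two-tailed unpaired t test (classic pooled-variance form;
  Welch available by flag),
* the unpaired two-sided Mann-Whitney U test (exact null for small
  tie-free samples, normal approximation with tie correction otherwise),
* Bonferroni-adjusted significance thresholds (the number of planned
  comparisons is always supplied by the caller, never inferred), and
* first-order uncertainty propagation for a ratio of two means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test: str  # "t_unpaired_two_tailed" | "mann_whitney_u"
    alpha_adjusted: float = 0.05
    degenerate: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def t_test_unpaired(
    x, y, alpha_adjusted: float = 0.05, welch: bool = False
) -> TestResult:
    """Student's two-tailed unpaired t test (pooled variance by default).

    Degenerate zero-variance inputs are handled explicitly: equal means give
    p = 1, unequal means give p = 0 with a degeneracy flag.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t test needs n >= 2 per group")
    degenerate = ""
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = math.inf if x.mean() > y.mean() else -math.inf, 0.0
        degenerate = "zero variance in both samples"
    else:
        stat, p = sstats.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n1=len(x),
        n2=len(y),
        test="t_unpaired_two_tailed",
        alpha_adjusted=alpha_adjusted,
        degenerate=degenerate,
    )


def mann_whitney_u(x, y, alpha_adjusted: float = 0.05) -> TestResult:
    """Unpaired two-sided Mann-Whitney U test.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    normal approximation with tie correction (and continuity correction)
    otherwise. All values tied across both groups gives p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("mann_whitney_u needs n >= 1 per group")
    pooled = np.concatenate([x, y])
    degenerate = ""
    if np.ptp(pooled) == 0:
        stat = len(x) * len(y) / 2.0
        p = 1.0
        degenerate = "all values tied"
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
        res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n1=len(x),
        n2=len(y),
        test="mann_whitney_u",
        alpha_adjusted=alpha_adjusted,
        degenerate=degenerate,
    )


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Per-comparison significance threshold alpha_family / m (full precision)."""
    if not (0 < alpha_family <= 1):
        raise ValueError("alpha_family must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha_family / m


def format_threshold(threshold: float) -> str:
    """Conservative display rounding for significance thresholds.

    Uses one significant figure when that neither overstates the threshold
    nor tightens it by more than 5%; otherwise truncates at two significant
    figures. This yields e.g. 0.05/11 -> "0.0045" and 0.05/7 -> "0.007"
    and never displays a threshold looser than the exact one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    one_sig = round(threshold, -exponent)
    tol = 1e-12 * threshold
    if one_sig <= threshold + tol and (threshold - one_sig) <= 0.05 * threshold + tol:
        value = one_sig
        decimals = -exponent
    else:
        scale = 10.0 ** (exponent - 1)
        value = math.floor(threshold / scale + 1e-12) * scale
        decimals = -(exponent - 1)
    return f"{value:.{max(decimals, 0)}f}"


def ratio_with_sd(
    a_mean: float, a_sd: float, b_mean: float, b_sd: float
) -> tuple[float, float]:
    """Ratio of two means with first-order (delta-method) uncertainty.

    fold = a/b; fold_sd = |fold| * sqrt((a_sd/a)^2 + (b_sd/b)^2). Valid when
    the relative uncertainties are small; b_mean <= 0 is undefined.
    """
    if b_mean <= 0:
        raise ValueError("ratio undefined: denominator mean must be positive")
    fold = a_mean / b_mean
    if a_mean == 0:
        return fold, abs(a_sd / b_mean)
    rel = math.sqrt((a_sd / a_mean) ** 2 + (b_sd / b_mean) ** 2)
    return fold, abs(fold) * rel
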