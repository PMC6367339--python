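"""Group comparisons and two-group linear-regression (ANCOVA-style) tests.

The regression comparison follows the classic sequential scheme used by
common graphing software: fit ordinary least squares per group, test slope
equality with an extra-sum-of-squares F-test (separate-slopes model vs
common-slope model); only if the slopes are compatible, test equality of
elevation (intercept under the common-slope model).  Per-group
deviation-from-zero p-values report whether each slope differs from 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "RegressionComparison",
    "compare_groups",
    "anova_tukey",
    "regression_compare",
    "percent_reduction",
]


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    note: str = ""
    groups: tuple[int, int] | None = None  # for pairwise post hoc results

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RegressionComparison:
    slope_a: float
    intercept_a: float
    r2_a: float
    p_zero_a: float      # slope-deviates-from-zero, group A
    slope_b: float
    intercept_b: float
    r2_b: float
    p_zero_b: float
    f_slope: float       # test of common slope
    p_slope: float
    f_elev: float | None  # test of equal elevation (only under common slope)
    p_elev: float | None
    common_slope: float | None
    slopes_differ: bool
    alpha: float = 0.05


def compare_groups(values_a, values_b, test: str = "student_t") -> GroupTestResult:
    """Two-sided two-group comparison.

    ``test``: ``student_t`` (classic pooled-variance Student t),
    ``welch_t`` (unequal variances), or ``mann_whitney_u`` (exact for small
    tie-free samples).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test in ("student_t", "welch_t"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-tests require n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                return GroupTestResult(test, 0.0, 1.0, len(a), len(b))
            return GroupTestResult(
                test, math.inf, 0.0, len(a), len(b),
                note="degenerate: zero variance in both groups, unequal means",
            )
        res = sps.ttest_ind(a, b, equal_var=(test == "student_t"))
        return GroupTestResult(test, float(res.statistic), float(res.pvalue),
                               len(a), len(b))
    if test == "mann_whitney_u":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("Mann-Whitney requires n >= 1 per group")
        method = "exact" if (len(a) + len(b) <= 30
                             and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) \
            else "auto"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupTestResult(test, float(res.statistic), float(res.pvalue),
                               len(a), len(b))
    raise ValueError(f"unknown test: {test!r}")


def anova_tukey(groups) -> tuple[GroupTestResult, list[GroupTestResult]]:
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    With fewer than three groups the comparison falls back to the
    two-group Student t-test.  Groups entirely identical give F = 0, p = 1
    and all pairwise p = 1.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in samples):
        raise ValueError("every group needs n >= 2")
    if len(samples) < 3:
        res = compare_groups(samples[0], samples[1], "student_t")
        return res, [GroupTestResult("tukey_hsd", res.statistic, res.p_value,
                                     len(samples[0]), len(samples[1]),
                                     groups=(0, 1))]
    allv = np.concatenate(samples)
    if np.all(allv == allv[0]):
        omnibus = GroupTestResult("anova", 0.0, 1.0, len(samples[0]), len(samples[1]),
                                  note="all groups identical")
        pw = [GroupTestResult("tukey_hsd", 0.0, 1.0, len(samples[i]), len(samples[j]),
                              groups=(i, j))
              for i in range(len(samples)) for j in range(i + 1, len(samples))]
        return omnibus, pw
    f, p = sps.f_oneway(*samples)
    omnibus = GroupTestResult("anova", float(f), float(p),
                              len(samples[0]), len(samples[1]))
    hsd = sps.tukey_hsd(*samples)
    pw = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            pw.append(GroupTestResult(
                "tukey_hsd", float(hsd.statistic[i, j]),
                float(hsd.pvalue[i, j]), len(samples[i]), len(samples[j]),
                groups=(i, j)))
    return omnibus, pw


def _ols_line(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    p_zero = float(res.pvalues[1])
    return slope, intercept, float(res.rsquared), p_zero, res


def regression_compare(x_a, y_a, x_b, y_b, alpha: float = 0.05) -> RegressionComparison:
    """Compare two linear regressions: slopes first, then elevation.

    Requires n >= 3 per group and non-degenerate x in each group.  The
    elevation (common-slope intercept) test is computed only when the
    slope-equality test is not rejected at ``alpha``, mirroring standard
    sequential reporting.
    """
    xa = np.asarray(x_a, dtype=float)
    ya = np.asarray(y_a, dtype=float)
    xb = np.asarray(x_b, dtype=float)
    yb = np.asarray(y_b, dtype=float)
    for x, name in ((xa, "A"), (xb, "B")):
        if len(x) < 3:
            raise ValueError(f"group {name} needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("degenerate predictor: x values are constant in a group")
    if len(xa) != len(ya) or len(xb) != len(yb):
        raise ValueError("x and y lengths differ")

    slope_a, int_a, r2_a, pz_a, _ = _ols_line(xa, ya)
    slope_b, int_b, r2_b, pz_b, _ = _ols_line(xb, yb)

    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])

    X_full = np.column_stack([np.ones_like(x), g, x, g * x])
    X_common = np.column_stack([np.ones_like(x), g, x])
    X_single = np.column_stack([np.ones_like(x), x])
    res_full = sm.OLS(y, X_full).fit()
    res_common = sm.OLS(y, X_common).fit()
    res_single = sm.OLS(y, X_single).fit()

    f_slope, p_slope, _ = res_full.compare_f_test(res_common)
    slopes_differ = p_slope < alpha
    if slopes_differ:
        f_elev = p_elev = common_slope = None
    else:
        f_e, p_e, _ = res_common.compare_f_test(res_single)
        f_elev, p_elev = float(f_e), float(p_e)
        common_slope = float(res_common.params[2])

    return RegressionComparison(
        slope_a=slope_a, intercept_a=int_a, r2_a=r2_a, p_zero_a=pz_a,
        slope_b=slope_b, intercept_b=int_b, r2_b=r2_b, p_zero_b=pz_b,
        f_slope=float(f_slope), p_slope=float(p_slope),
        f_elev=f_elev, p_elev=p_elev, common_slope=common_slope,
        slopes_differ=bool(slopes_differ), alpha=alpha,
    )


def percent_reduction(reference: float, value: float) -> float:
    """Percent reduction of ``value`` relative to ``reference``.

    E.g. muscle-mass hypotrophy: 100 × (m_ref − m) / m_ref.
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - value) / reference
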