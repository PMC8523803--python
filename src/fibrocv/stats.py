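"""Statistical reporting for cohort comparisons and CV-vs-fibrosis trends.

Group comparisons use Welch's unequal-variance t-test, one-way ANOVA across
the three study groups, and two-sample variance-ratio (F) tests; trends are
summarized by ordinary least-squares fits y = A x + B evaluated against a
constant model.  The significance threshold is fixed at 0.05 and no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "welch_t",
    "group_tests",
    "variance_f_test",
    "linreg",
    "regression_table",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    p_vs_constant: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_vs_constant < ALPHA


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's t statistic and two-sided p (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def variance_f_test(group_a, group_b) -> tuple[float, float]:
    """Two-sample variance-ratio F test (two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero-variance group in variance-ratio test")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    return float(f), float(2 * min(cdf, 1 - cdf))


def group_tests(values_by_group: dict) -> dict:
    """One-way ANOVA plus pairwise variance-ratio tests over named groups.

    Returns ``{"anova_F", "anova_p", "variance_f": {(a, b): (F, p)}}``.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[k], dtype=float) for k in names]
    F, p = sps.f_oneway(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = variance_f_test(arrays[i], arrays[j])
    return {"anova_F": float(F), "anova_p": float(p), "variance_f": pairwise}


def linreg(x, y) -> RegressionFit:
    """OLS line y = A x + B with R^2 and the F-test p against a constant model.

    For the simple linear model the F test against the intercept-only model
    is identical to the two-sided t test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_vs_constant=float(res.pvalue),
        n=len(x),
    )


def regression_table(frame: pd.DataFrame, pairs) -> pd.DataFrame:
    """Fit y = A x + B for each (x_column, y_column) pair of ``frame``.

    Rows with NaN in either column are dropped per pair.  Output mirrors a
    regression summary table: x, y, A, B, R^2, p.
    """
    rows = []
    for xcol, ycol in pairs:
        sub = frame[[xcol, ycol]].dropna()
        fit = linreg(sub[xcol], sub[ycol])
        rows.append(
            {
                "x": xcol,
                "y": ycol,
                "A": fit.slope,
                "B": fit.intercept,
                "R2": fit.r2,
                "p": fit.p_vs_constant,
                "n": fit.n,
                "significant": fit.significant,
            }
        )
    return pd.DataFrame(rows)
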