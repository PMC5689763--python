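"""Cohort-level summary statistics.

The three tests used for cohort relationships: ordinary least-squares
regression (r^2 and the two-sided slope p-value) for relations against
predetermined variables such as administered dose, the Spearman rank
correlation for relations between measured quantities, and the Welch
(unequal-variance) two-sample t test for group comparisons.  No
multiple-testing correction is applied; raw p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "linear_regression_r2",
    "spearman_r",
    "welch_t_test",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.method}: stat={self.statistic:.4g}, p={self.p_value:.3g}, n={self.n}"


def _clean_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D arrays")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if len(x) < min_n:
        raise ValueError(f"at least {min_n} observations required")
    return x, y


def linear_regression_r2(x, y) -> StatResult:
    """OLS of y on x: returns r^2 and the two-sided slope p-value."""
    x, y = _clean_xy(x, y, min_n=3)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: x has zero variance")
    fit = sps.linregress(x, y)
    return StatResult(
        statistic=fit.rvalue**2,
        p_value=float(fit.pvalue),
        n=len(x),
        method="OLS r^2",
    )


def spearman_r(x, y) -> StatResult:
    """Spearman rank correlation (mid-ranks for ties), two-sided p."""
    x, y = _clean_xy(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for an all-tied vector")
    r, p = sps.spearmanr(x, y)
    return StatResult(statistic=float(r), p_value=float(p), n=len(x), method="Spearman r")


def welch_t_test(a, b) -> StatResult:
    """Two-tailed two-sample t test with unequal variances (Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("t statistic undefined: both groups constant and equal")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        statistic=float(t), p_value=float(p), n=len(a) + len(b), method="Welch t"
    )
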