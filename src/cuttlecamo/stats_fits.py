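"""Group comparisons and trend fits over per-crossing reflectance changes.

The experimental unit is the crossing.  Groups are the control condition
plus one group per patch width.  The omnibus comparison is the
Kruskal-Wallis rank test (chi-square approximation with tie correction);
the patch width at which behavior departs from control is found by
pairwise two-sided Wilcoxon rank-sum tests against control in increasing
width order, uncorrected by default (a Holm option is provided).

Trend fits follow the three families used for the patch-size relations:
linear (mean change vs width), logarithmic (transition slopes vs width,
``y = a ln x + b`` with x-intercept ``exp(-b/a)``) and a four-parameter
logistic (change variance vs width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "kruskal_wallis",
    "first_significant_patch",
    "pearson_r",
    "fit_linear",
    "fit_logarithmic",
    "fit_sigmoid4",
    "sigmoid4",
]

CONTROL = "control"


@dataclass(frozen=True)
class FitResult:
    model: str
    coefficients: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    x_intercept: float | None = None
    success: bool = True

    def __post_init__(self) -> None:
        if self.success and not np.isnan(self.r_squared) and self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def kruskal_wallis(groups: dict | list) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; returns (H, df, p).

    If every pooled observation is identical, H is defined as 0 with
    p = 1 (no evidence of any difference).
    """
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), df, float(p)


def first_significant_patch(
    groups: dict,
    alpha: float = 0.05,
    holm: bool = False,
    method: str = "exact",
) -> float | None:
    """Smallest patch width whose changes differ from control.

    Runs the Kruskal-Wallis omnibus over all groups; if significant,
    performs two-sided Wilcoxon rank-sum tests of each width against
    control in increasing width order and returns the smallest width with
    p < alpha.  ``holm=True`` applies a Holm step-down correction over the
    pairwise family instead of using raw p-values.
    """
    if CONTROL not in groups:
        raise ValueError("groups must contain a 'control' entry")
    control = np.asarray(groups[CONTROL], dtype=float)
    widths = sorted(k for k in groups if k != CONTROL)
    _, _, p_omni = kruskal_wallis(groups)
    if p_omni >= alpha:
        return None
    pvals = {}
    for w in widths:
        res = stats.mannwhitneyu(
            np.asarray(groups[w], dtype=float),
            control,
            alternative="two-sided",
            method=method if method != "exact" else "exact",
        )
        pvals[w] = float(res.pvalue)
    if holm:
        order = sorted(widths, key=lambda w: pvals[w])
        m = len(order)
        adj, running = {}, 0.0
        for rank, w in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[w]))
            adj[w] = running
        pvals = adj
    for w in widths:
        if pvals[w] < alpha:
            return w
    return None


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fit_linear(x, y) -> FitResult:
    """Ordinary least-squares line ``y = slope * x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    return FitResult(
        model="linear",
        coefficients={"slope": float(slope), "intercept": float(intercept)},
        r_squared=_r_squared(y, yhat),
        x_intercept=float(-intercept / slope) if slope != 0 else None,
    )


def fit_logarithmic(x, y) -> FitResult:
    """Least squares of ``y = a ln(x) + b`` (x > 0); reports the x-axis
    interception point ``exp(-b/a)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("logarithmic fit requires positive x")
    a, b = np.polyfit(np.log(x), y, 1)
    yhat = a * np.log(x) + b
    # a finite x-intercept only exists for a non-degenerate slope
    intercept = float(np.exp(-b / a)) if a != 0 and abs(b / a) < 500 else None
    return FitResult(
        model="logarithmic",
        coefficients={"a": float(a), "b": float(b)},
        r_squared=_r_squared(y, yhat),
        x_intercept=intercept,
    )


def sigmoid4(x, lower, upper, x0, k):
    """Four-parameter logistic."""
    from scipy.special import expit

    return lower + (upper - lower) * expit(k * (np.asarray(x, float) - x0))


def fit_sigmoid4(x, y) -> FitResult:
    """Nonlinear least-squares 4-parameter logistic fit.

    Initial values: lower = min y, upper = max y, x0 = median x, k = 1.
    Non-convergence or degenerate (constant) input is reported as a
    failed fit rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    if np.all(y == y[0]):
        return FitResult(model="sigmoid4", success=False)
    p0 = (float(y.min()), float(y.max()), float(np.median(x)), 1.0)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(sigmoid4, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return FitResult(model="sigmoid4", success=False)
    yhat = sigmoid4(x, *popt)
    return FitResult(
        model="sigmoid4",
        coefficients=dict(zip(("lower", "upper", "x0", "k"), map(float, popt))),
        r_squared=_r_squared(y, yhat),
    )


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot
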