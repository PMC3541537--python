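"""Correlation estimators: Pearson, Spearman, percentage-bend, skipped.

The two robust estimators embody complementary protection strategies.
The percentage-bend correlation Winsorises each margin's standardised
deviations at +/-1 after estimating a bend scale from the (1 - beta)
empirical quantile of absolute deviations from the median, guarding
against marginal outliers.  The skipped correlations remove bivariate
outliers found by the projection method and then compare the usual t
statistic against a simulation-calibrated critical value that accounts
for the removal — the naive t quantile would be anti-conservative
because outlier rejection induces dependence among the retained points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .outliers import OutlierReport, bivariate_outliers

__all__ = [
    "CorrelationResult",
    "BendDetail",
    "pearson",
    "spearman",
    "percentage_bend",
    "skipped",
    "skipped_critical_t",
]


@dataclass
class CorrelationResult:
    """Outcome of one correlation test.

    ``p`` is None for skipped methods, whose decision ``h`` comes from
    comparing ``T`` with ``critical_value``.  ``r`` is NaN when the
    estimate is undefined (see ``reason``).
    """

    method: str
    r: float
    T: float
    n: int
    n_used: int
    h: int
    p: float | None = None
    df: int | None = None
    critical_value: float | None = None
    alpha: float = 0.05
    ci: tuple[float, float] | None = None
    outlier_report: OutlierReport | None = None
    reason: str | None = None


@dataclass
class BendDetail:
    """Intermediate quantities of the percentage-bend computation."""

    beta: float
    omega_x: float
    omega_y: float
    theta_x: float
    theta_y: float
    bent_mask_x: np.ndarray = field(default_factory=lambda: np.array([], bool))
    bent_mask_y: np.ndarray = field(default_factory=lambda: np.array([], bool))


def _check_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def _t_and_p(r: float, n: int) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return float(np.inf) if r > 0 else float(-np.inf), 0.0
    T = r * np.sqrt((n - 2) / (1 - r * r))
    return float(T), float(2 * stats.t.sf(abs(T), n - 2))


def pearson(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with the Student-t test (n - 2 df)."""
    x, y = _check_pair(x, y, 3)
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate margin: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    T, p = _t_and_p(r, n)
    return CorrelationResult("pearson", r, T, n, n, int(p < alpha),
                             p=p, df=n - 2, alpha=alpha)


def spearman(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman's rho: Pearson's r on midranks, t-approximate p-value."""
    x, y = _check_pair(x, y, 3)
    res = pearson(stats.rankdata(x), stats.rankdata(y), alpha=alpha)
    res.method = "spearman"
    return res


def _bend_margin(v: np.ndarray, beta: float):
    n = len(v)
    M = np.median(v)
    W = np.sort(np.abs(v - M))
    m = int(np.floor((1 - beta) * n))
    omega = W[m - 1]
    if omega <= 0:
        raise ValueError("degenerate margin: bend scale is zero")
    U = (v - M) / omega
    i1 = int((U < -1).sum())
    i2 = int((U > 1).sum())
    theta = (v[np.abs(U) <= 1].sum() + omega * (i2 - i1)) / (n - i1 - i2)
    if beta == 0:
        # bend none of the observations: theta is the mean and the scale
        # cancels, reducing exactly to Pearson
        return (v - theta) / omega, float(omega), float(theta), \
            np.zeros(n, dtype=bool)
    A = np.clip((v - theta) / omega, -1.0, 1.0)
    bent = np.abs((v - theta) / omega) > 1
    return A, float(omega), float(theta), bent


def percentage_bend(x, y, beta: float = 0.2,
                    alpha: float = 0.05) -> tuple[CorrelationResult, BendDetail]:
    """Percentage-bend correlation.

    Per margin: M = median; omega = the floor((1 - beta) n)-th order
    statistic of |v - M|; theta = a one-step location update counting
    points bent past +/- omega; A_i = psi((v_i - theta) / omega) with psi
    clipping at +/-1.  r is the product-moment formula on the A's and
    B's; the t test uses n - 2 df.  beta = 0 reduces exactly to Pearson.

    r = +/-1 reports p = 0.
    """
    x, y = _check_pair(x, y, 4)
    if not 0 <= beta < 0.5:
        raise ValueError("beta must be in [0, 0.5)")
    n = len(x)
    A, om_x, th_x, bent_x = _bend_margin(x, beta)
    B, om_y, th_y, bent_y = _bend_margin(y, beta)
    denom = np.sqrt((A * A).sum() * (B * B).sum())
    if denom == 0:
        raise ValueError("degenerate margin: all values bent to the median")
    r = float((A * B).sum() / denom)
    r = min(1.0, max(-1.0, r))
    T, p = _t_and_p(r, n)
    res = CorrelationResult("percentage-bend", r, T, n, n, int(p < alpha),
                            p=p, df=n - 2, alpha=alpha)
    return res, BendDetail(beta, om_x, om_y, th_x, th_y, bent_x, bent_y)


def skipped_critical_t(n: int) -> float:
    """Critical |t| for the skipped correlation at alpha = 0.05.

    Wilcox's simulation-derived approximation 6.947 / n + 2.3197,
    indexed by the ORIGINAL sample size n (not the post-removal count),
    which is how the test accounts for outlier removal.
    """
    if n < 5:
        raise ValueError("need at least 5 observations")
    return 6.947 / n + 2.3197


def skipped(x, y, estimator: str = "pearson", alpha: float = 0.05,
            seed: int | None = None, rule: str = "boxplot",
            h_fraction: float = 0.75) -> CorrelationResult:
    """Skipped correlation: estimate after removing bivariate outliers.

    Outliers are flagged by the projection method anchored at the MCD
    center; the chosen estimator (``"pearson"`` or ``"spearman"``) is
    computed on the retained points, and H0 is rejected when |T| exceeds
    ``skipped_critical_t(n)``.  Only alpha = 0.05 is supported for the
    decision (the critical-value approximation was calibrated there);
    other levels should use the bootstrap CI.

    When removal leaves fewer than 3 points or a constant margin the
    estimate is undefined: r = NaN, h = 0, with a reason code.
    """
    x, y = _check_pair(x, y, 5)
    if estimator not in ("pearson", "spearman"):
        raise ValueError("estimator must be 'pearson' or 'spearman'")
    if alpha != 0.05:
        raise ValueError("the skipped decision is calibrated for alpha = 0.05 only")
    n = len(x)
    report = bivariate_outliers(x, y, rule=rule, h_fraction=h_fraction, seed=seed)
    keep = ~report.flags
    xs, ys = x[keep], y[keep]
    m = len(xs)
    tcrit = skipped_critical_t(n)
    name = f"skipped-{estimator}"
    if m < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        reason = "fewer than 3 points retained" if m < 3 else \
            "constant margin after outlier removal"
        return CorrelationResult(name, float("nan"), float("nan"), n, m, 0,
                                 critical_value=tcrit, alpha=alpha,
                                 outlier_report=report, reason=reason)
    if estimator == "spearman":
        xs, ys = stats.rankdata(xs), stats.rankdata(ys)
    r = float(np.corrcoef(xs, ys)[0, 1])
    if abs(r) >= 1.0:
        T = float(np.inf) if r > 0 else float(-np.inf)
    else:
        T = float(r * np.sqrt((m - 2) / (1 - r * r)))
    return CorrelationResult(name, r, T, n, m, int(abs(T) > tcrit),
                             critical_value=tcrit, alpha=alpha,
                             outlier_report=report)
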