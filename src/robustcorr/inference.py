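"""Bootstrap confidence intervals and assumption checks.

Percentile-bootstrap CIs resample pairs with replacement (for skipped
methods the already-cleaned pairs; outlier detection is not re-run per
resample) and read the interval off the sorted statistic values.  The CI
doubles as a heteroscedasticity-tolerant null test: reject independence
when 0 lies outside it.  The variance-homogeneity test bootstraps
var(x) - var(y) with Wilcox's small-sample-adjusted percentile indices.
The Henze-Zirkler statistic tests bivariate normality (smoothness-
weighted distance between the empirical and normal characteristic
functions), with the usual lognormal null approximation for its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlations import _bend_margin, _check_pair, skipped

__all__ = [
    "BootstrapCI",
    "NormalityResult",
    "VarianceTestResult",
    "bootstrap_ci",
    "variance_homogeneity",
    "henze_zirkler",
    "conditional_moments",
    "levene",
]

# Wilcox's adjusted percentile order statistics for B = 599 (1-based)
_ADJUSTED_B = 599
_ADJUSTED_IDX = [(40, (7, 593)), (80, (8, 592)), (180, (11, 588)),
                 (250, (14, 585)), (np.inf, (15, 584))]


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    B: int
    alpha: float
    adjusted: bool
    n_invalid_redraws: int

    @property
    def h(self) -> int:
        """Reject-independence indicator: 1 iff 0 is outside the CI."""
        return int(not (self.lower <= 0.0 <= self.upper))


@dataclass
class NormalityResult:
    HZ: float
    p: float
    beta_smooth: float
    n: int
    p_dim: int


@dataclass
class VarianceTestResult:
    var_x: float
    var_y: float
    diff: float
    ci: BootstrapCI
    h: int


def _corr_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r per row of paired resample matrices."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    return num / den


def _bend_rows(xs: np.ndarray, ys: np.ndarray, beta: float) -> np.ndarray:
    out = np.empty(len(xs))
    for i in range(len(xs)):
        A, *_ = _bend_margin(xs[i], beta)
        B_, *_ = _bend_margin(ys[i], beta)
        out[i] = (A * B_).sum() / np.sqrt((A * A).sum() * (B_ * B_).sum())
    return out


def _resample_valid(x: np.ndarray, y: np.ndarray, B: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw B paired resamples, redrawing any with a constant margin."""
    n = len(x)
    idx = rng.integers(0, n, size=(B, n))
    xs, ys = x[idx], y[idx]
    invalid = (np.ptp(xs, axis=1) == 0) | (np.ptp(ys, axis=1) == 0)
    redraws = 0
    attempts = 0
    while invalid.any():
        k = int(invalid.sum())
        attempts += k
        if attempts > 100 * B:
            raise RuntimeError("could not draw valid resamples "
                               "(margins nearly constant)")
        redraws += k
        idx_new = rng.integers(0, n, size=(k, n))
        xs[invalid], ys[invalid] = x[idx_new], y[idx_new]
        invalid = (np.ptp(xs, axis=1) == 0) | (np.ptp(ys, axis=1) == 0)
    return xs, ys, redraws


def _percentile_bounds(values: np.ndarray, alpha: float,
                       adjusted: bool, n: int) -> tuple[float, float]:
    s = np.sort(values)
    B = len(s)
    if adjusted:
        for bound, (lo, hi) in _ADJUSTED_IDX:
            if n < bound:
                return float(s[lo - 1]), float(s[hi - 1])
    a = int(np.floor(alpha / 2 * B))
    return float(s[a]), float(s[B - a - 1])


def bootstrap_ci(x, y, statistic: str = "pearson", B: int = 1000,
                 alpha: float = 0.05, seed: int | None = None,
                 beta: float = 0.2, adjusted: bool = False,
                 h_fraction: float = 0.75) -> BootstrapCI:
    """Percentile bootstrap CI for a correlation statistic.

    ``statistic`` is one of ``pearson``, ``spearman``, ``bend``,
    ``skipped-pearson``, ``skipped-spearman``.  For skipped statistics
    the bivariate outliers are removed once from the full sample and the
    cleaned pairs are resampled with the plain estimator.  Resamples in
    which either margin is a single repeated value are invalid and are
    redrawn (their count is reported).  ``adjusted=True`` uses Wilcox's
    small-sample order-statistic indices and forces B = 599.
    """
    x, y = _check_pair(x, y, 5)
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)

    if statistic.startswith("skipped-"):
        base = statistic.split("-", 1)[1]
        res = skipped(x, y, estimator=base, seed=seed, h_fraction=h_fraction)
        if not np.isfinite(res.r):
            return BootstrapCI(float("nan"), float("nan"),
                               B, alpha, adjusted, 0)
        keep = ~res.outlier_report.flags
        x, y = x[keep], y[keep]
        statistic = base

    if statistic == "pearson" and (np.std(x) == 0 or np.std(y) == 0):
        raise ValueError("degenerate margin: zero variance")

    if adjusted:
        B = _ADJUSTED_B
    xs, ys, redraws = _resample_valid(x, y, B, rng)
    if statistic == "pearson":
        vals = _corr_rows(xs, ys)
    elif statistic == "spearman":
        vals = _corr_rows(stats.rankdata(xs, axis=1), stats.rankdata(ys, axis=1))
    elif statistic == "bend":
        vals = _bend_rows(xs, ys, beta)
    else:
        raise ValueError(f"unknown statistic '{statistic}'")
    lo, hi = _percentile_bounds(vals, alpha, adjusted, len(x))
    return BootstrapCI(lo, hi, B, alpha, adjusted, redraws)


def variance_homogeneity(x, y, B: int = 599, seed: int | None = None,
                         adjusted: bool = True) -> VarianceTestResult:
    """Bootstrap test of var(x) = var(y) for paired data.

    Pairs are resampled together; each resample contributes
    var(x*) - var(y*).  The percentile CI uses the small-sample-adjusted
    indices by default (B is then fixed at 599); homogeneity is rejected
    when 0 falls outside the CI.
    """
    x, y = _check_pair(x, y, 8)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate margin: zero variance")
    rng = np.random.default_rng(seed)
    if adjusted:
        B = _ADJUSTED_B
    n = len(x)
    idx = rng.integers(0, n, size=(B, n))
    diffs = np.var(x[idx], axis=1, ddof=1) - np.var(y[idx], axis=1, ddof=1)
    lo, hi = _percentile_bounds(diffs, 0.05, adjusted, n)
    ci = BootstrapCI(lo, hi, B, 0.05, adjusted, 0)
    return VarianceTestResult(float(np.var(x, ddof=1)), float(np.var(y, ddof=1)),
                              float(np.var(x, ddof=1) - np.var(y, ddof=1)),
                              ci, ci.h)


def henze_zirkler(x, y) -> NormalityResult:
    """Henze-Zirkler test of bivariate normality.

    Uses the maximum-likelihood (1/n) sample covariance, the standard
    smoothing parameter beta = ((n (2p + 1)) / 4)^(1/(p+4)) / sqrt(2)
    with p = 2, and the lognormal approximation to the null distribution
    for the p-value.
    """
    x, y = _check_pair(x, y, 8)
    X = np.column_stack([x, y])
    n, p = X.shape
    S = np.cov(X, rowvar=False, bias=True)
    det = np.linalg.det(S)
    if det <= 1e-12 * (np.trace(S) ** p + 1e-300):
        raise np.linalg.LinAlgError("degenerate covariance")
    Si = np.linalg.inv(S)
    d = X - X.mean(axis=0)
    Dj = np.einsum("ij,jk,ik->i", d, Si, d)
    diff = d[:, None, :] - d[None, :, :]
    Djk = np.einsum("ijk,kl,ijl->ij", diff, Si, diff)
    b = ((n * (2 * p + 1)) / 4) ** (1 / (p + 4)) / np.sqrt(2)
    HZ = n * (np.exp(-b * b / 2 * Djk).mean()
              - 2 * (1 + b * b) ** (-p / 2)
              * np.mean(np.exp(-b * b / (2 * (1 + b * b)) * Dj))
              + (1 + 2 * b * b) ** (-p / 2))
    # lognormal null moments
    a = 1 + 2 * b * b
    wb = (1 + b * b) * (1 + 3 * b * b)
    mu = 1 - a ** (-p / 2) * (1 + p * b * b / a
                              + p * (p + 2) * b ** 4 / (2 * a * a))
    si2 = (2 * (1 + 4 * b * b) ** (-p / 2)
           + 2 * a ** (-p) * (1 + 2 * p * b ** 4 / a ** 2
                              + 3 * p * (p + 2) * b ** 8 / (4 * a ** 4))
           - 4 * wb ** (-p / 2) * (1 + 3 * p * b ** 4 / (2 * wb)
                                   + p * (p + 2) * b ** 8 / (2 * wb * wb)))
    pmu = np.log(np.sqrt(mu ** 4 / (si2 + mu * mu)))
    psi = np.sqrt(np.log((si2 + mu * mu) / (mu * mu)))
    pval = float(stats.lognorm.sf(HZ, psi, scale=np.exp(pmu)))
    return NormalityResult(float(HZ), pval, float(b), n, p)


def conditional_moments(x, y, n_bins: int = 5):
    """Conditional means and variances in equal-count bins, both directions.

    Returns ``{"y|x": (centers, means, variances), "x|y": ...}`` where
    bins are formed on the conditioning margin.  Flat conditional means
    and variances are what independence plus homoscedasticity predict;
    trends diagnose association, fanning diagnoses heteroscedasticity.
    """
    x, y = _check_pair(x, y, 3 * n_bins)
    out = {}
    for key, cond, other in (("y|x", x, y), ("x|y", y, x)):
        order = np.argsort(cond, kind="stable")
        chunks = np.array_split(order, n_bins)
        centers = np.array([cond[c].mean() for c in chunks])
        means = np.array([other[c].mean() for c in chunks])
        variances = np.array([other[c].var(ddof=1) for c in chunks])
        out[key] = (centers, means, variances)
    return out


def levene(x, y) -> tuple[float, float]:
    """Classical (mean-centered) Levene test of var(x) = var(y).

    One-way ANOVA F on |v - mean| with df (1, 2n - 2); included as the
    low-power textbook baseline the bootstrap test improves on.
    """
    x, y = _check_pair(x, y, 3)
    F, p = stats.levene(x, y, center="mean")
    return float(F), float(p)
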