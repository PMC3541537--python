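"""Monte-Carlo validation harness: population generators, false-positive /
power grids, and the worked examples.

Populations are bivariate normal with unit variances and correlation rho,
optionally contaminated by replacing ``round(prop * n)`` points with draws
from a second unit-variance normal population whose mean is displaced to
[6, 0] (marginal outliers: extreme in x only) or [6, 6] (bivariate
outliers) and whose correlation is ``-rho``.  Samples are drawn directly
from the model distributions; every method sees the same draws so that
method comparisons are paired.

The heavy lifting (skipped correlations over thousands of replicates) is
vectorised: for n <= 12 the exhaustive MCD, the reweighting step and the
projection rule all run as batched array operations, and the per-sample
results agree exactly with the public single-sample API (this is asserted
in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .center import _consistency_factor, _cstep_raw, _CHI2_975_2
from .correlations import skipped_critical_t
from .datasets import anscombe
from .outliers import GATE_0975, _projection_flags

__all__ = [
    "PopulationSpec",
    "SimulationGridResult",
    "N_GRID_FULL",
    "N_GRID_REDUCED",
    "gen_bivariate_normal",
    "gen_contaminated",
    "run_fpr_power",
    "effect_size_bias",
    "compare_methods_median_diff",
    "schwarzkopf_sim",
    "rotating_outlier_demo",
    "anscombe",
]

#: the sample sizes of the validation study
N_GRID_FULL = (10, 20, 30, 40, 50, 60, 80, 100, 150, 200, 250, 300, 400, 500)
#: desk-scale grid for the expensive skipped-correlation scenarios
N_GRID_REDUCED = (10, 20, 50, 100, 200)

_METHODS = ("pearson", "spearman", "bend",
            "skipped-pearson", "skipped-spearman")


@dataclass
class PopulationSpec:
    """Study population: main correlation plus an optional contamination.

    ``contamination`` is ``"none"``, ``"marginal"`` (outlier mean [6, 0])
    or ``"bivariate"`` (outlier mean [6, 6]); the outlier population has
    unit variances and correlation ``-rho``, and replaces
    ``round(prop * n)`` points of each sample.
    """

    rho: float = 0.0
    contamination: str = "none"
    prop: float = 0.10

    def __post_init__(self):
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")
        if self.contamination not in ("none", "marginal", "bivariate"):
            raise ValueError("contamination must be none|marginal|bivariate")

    @property
    def outlier_mean(self) -> np.ndarray:
        return np.array([6.0, 0.0]) if self.contamination == "marginal" \
            else np.array([6.0, 6.0])


@dataclass
class SimulationGridResult:
    """Tidy per-(rho, n, method) summary plus optional replicate-level r."""

    table: pd.DataFrame
    replicates: dict = field(default_factory=dict)
    seed: int | None = None


def _normal_pairs(rng: np.random.Generator, shape, rho: float) -> np.ndarray:
    z = rng.standard_normal(shape + (2,))
    out = np.empty_like(z)
    out[..., 0] = z[..., 0]
    out[..., 1] = rho * z[..., 0] + np.sqrt(1 - rho * rho) * z[..., 1]
    return out


def gen_bivariate_normal(n: int, rho: float, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """n pairs from the standard bivariate normal with correlation rho."""
    if not -1 <= rho <= 1:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    P = _normal_pairs(rng, (n,), rho)
    return P[:, 0], P[:, 1]


def gen_contaminated(n: int, spec: PopulationSpec,
                     seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Sample from ``spec``: main population plus displaced outliers.

    ``round(spec.prop * n)`` randomly-positioned points are replaced by
    draws from the outlier population (unit variances, correlation
    ``-spec.rho``, mean ``spec.outlier_mean``).
    """
    rng = np.random.default_rng(seed)
    P = _batch_contaminated(rng, 1, n, spec)[0]
    return P[:, 0], P[:, 1]


def _batch_contaminated(rng: np.random.Generator, reps: int, n: int,
                        spec: PopulationSpec) -> np.ndarray:
    S = _normal_pairs(rng, (reps, n), spec.rho)
    if spec.contamination == "none" or spec.prop == 0:
        return S
    k = int(round(spec.prop * n))
    if k < 1:
        raise ValueError("contamination proportion rounds to zero points")
    out = _normal_pairs(rng, (reps, k), -spec.rho) + spec.outlier_mean
    # random substitution positions, independently per replicate
    pos = np.argsort(rng.random((reps, n)), axis=1)[:, :k]
    np.put_along_axis(S, pos[:, :, None].repeat(2, axis=2), out, axis=1)
    return S


# ---------------------------------------------------------------------------
# batched estimators


def _batch_pearson(S: np.ndarray, mask: np.ndarray | None = None):
    """Pearson r per replicate, optionally over a retained-point mask.

    Returns (r, m) with r = NaN where fewer than 3 points remain or a
    margin is constant.
    """
    x, y = S[..., 0], S[..., 1]
    if mask is None:
        mask = np.ones(x.shape, dtype=bool)
    k = mask.astype(float)
    m = k.sum(axis=1)
    safe_m = np.where(m == 0, 1, m)
    sx = (k * x).sum(axis=1)
    sy = (k * y).sum(axis=1)
    vx = (k * x * x).sum(axis=1) - sx * sx / safe_m
    vy = (k * y * y).sum(axis=1) - sy * sy / safe_m
    cxy = (k * x * y).sum(axis=1) - sx * sy / safe_m
    scale = (k * x * x).sum(axis=1) + (k * y * y).sum(axis=1) + 1e-300
    ok = (m >= 3) & (vx > 1e-12 * scale) & (vy > 1e-12 * scale)
    r = np.full(len(S), np.nan)
    r[ok] = cxy[ok] / np.sqrt(vx[ok] * vy[ok])
    r[ok] = np.clip(r[ok], -1.0, 1.0)
    return r, m


def _batch_spearman(S: np.ndarray):
    R = np.stack([stats.rankdata(S[..., 0], axis=1),
                  stats.rankdata(S[..., 1], axis=1)], axis=-1)
    return _batch_pearson(R)[0]


def _batch_bend(S: np.ndarray, beta: float = 0.2):
    """Percentage-bend r per replicate (vectorised over replicates)."""
    reps, n, _ = S.shape
    m_idx = int(np.floor((1 - beta) * n))
    AB = []
    for c in (0, 1):
        v = S[..., c]
        M = np.median(v, axis=1, keepdims=True)
        W = np.sort(np.abs(v - M), axis=1)
        omega = W[:, m_idx - 1][:, None]
        omega = np.where(omega <= 0, np.nan, omega)
        U = (v - M) / omega
        i1 = (U < -1).sum(axis=1)
        i2 = (U > 1).sum(axis=1)
        inner = np.where(np.abs(U) <= 1, v, 0.0).sum(axis=1)
        theta = (inner + omega[:, 0] * (i2 - i1)) / (n - i1 - i2)
        AB.append(np.clip((v - theta[:, None]) / omega, -1.0, 1.0))
    A, B = AB
    return (A * B).sum(axis=1) / np.sqrt((A * A).sum(axis=1) * (B * B).sum(axis=1))


_SUBSET_CACHE: dict = {}


def _exhaustive_subsets(n: int, h: int) -> np.ndarray:
    key = (n, h)
    if key not in _SUBSET_CACHE:
        _SUBSET_CACHE[key] = np.array(list(combinations(range(n), h)))
    return _SUBSET_CACHE[key]


def _batch_mcd_centers_small(S: np.ndarray, h_fraction: float = 0.75) -> np.ndarray:
    """Reweighted exhaustive MCD centers for a batch of samples, n <= 12.

    Mirrors ``center.mcd_estimate`` exactly (raw h-subset with minimal
    determinant, consistency scaling, chi-square 0.975 reweighting).
    """
    reps, n, _ = S.shape
    h = max(int(np.floor(h_fraction * n)), (n + 3) // 2)
    subs = _exhaustive_subsets(n, h)
    X = S[:, subs, :]                         # (reps, m, h, 2)
    mu = X.mean(axis=2)
    C = X - mu[:, :, None, :]
    cov = np.einsum("rmhi,rmhj->rmij", C, C) / (h - 1)
    det = cov[..., 0, 0] * cov[..., 1, 1] - cov[..., 0, 1] ** 2
    best = det.argmin(axis=1)
    ar = np.arange(reps)
    c0 = mu[ar, best]
    cv = cov[ar, best] * _consistency_factor(h / n)
    d0 = det[ar, best]
    ok = d0 > 1e-12
    inv = np.empty_like(cv)
    inv[:, 0, 0] = cv[:, 1, 1]
    inv[:, 1, 1] = cv[:, 0, 0]
    inv[:, 0, 1] = -cv[:, 0, 1]
    inv[:, 1, 0] = -cv[:, 1, 0]
    deti = cv[:, 0, 0] * cv[:, 1, 1] - cv[:, 0, 1] ** 2
    inv /= np.where(deti == 0, 1.0, deti)[:, None, None]
    d = S - c0[:, None, :]
    d2 = np.einsum("rni,rij,rnj->rn", d, inv, d)
    w = (d2 <= _CHI2_975_2) & ok[:, None]
    cnt = w.sum(axis=1)
    use = ok & (cnt >= 3)
    centers = c0.copy()
    sums = np.einsum("rn,rni->ri", w.astype(float), S)
    centers[use] = sums[use] / cnt[use, None]
    return centers


def _center_large(P: np.ndarray, rng: np.random.Generator,
                  h_fraction: float = 0.75) -> np.ndarray:
    """Reweighted FAST-MCD center for a single sample, n > 12."""
    n = len(P)
    h = max(int(np.floor(h_fraction * n)), (n + 3) // 2)
    _, mu, cov, det = _cstep_raw(P, h, rng)
    if det < 1e-12:
        return mu
    cv = cov * _consistency_factor(h / n)
    inv = np.array([[cv[1, 1], -cv[0, 1]], [-cv[1, 0], cv[0, 0]]])
    inv /= cv[0, 0] * cv[1, 1] - cv[0, 1] ** 2
    d = P - mu
    d2 = np.einsum("ni,ij,nj->n", d, inv, d)
    w = d2 <= _CHI2_975_2
    if w.sum() < 3:
        return mu
    return P[w].mean(axis=0)


def _batch_skipped(S: np.ndarray, rng: np.random.Generator,
                   estimator: str = "pearson", rule: str = "boxplot",
                   gate: float = GATE_0975, h_fraction: float = 0.75):
    """Skipped correlation per replicate.

    Returns (r, reject, n_undefined); undefined replicates have r = NaN
    and count as non-rejections.
    """
    reps, n, _ = S.shape
    if n <= 12:
        centers = _batch_mcd_centers_small(S, h_fraction)
    else:
        centers = np.empty((reps, 2))
        for i in range(reps):
            centers[i] = _center_large(S[i], rng, h_fraction)
    C = S - centers[:, None, :]
    G = np.einsum("rni,rmi->rnm", C, C)
    norms = np.sqrt((C ** 2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        D = G / norms[:, :, None]
    D = np.where(norms[:, :, None] == 0, 0.0, D)
    flags = _projection_flags(D, rule, gate)[0]
    if estimator == "spearman":
        # rank the retained points only, per replicate
        r = np.full(reps, np.nan)
        m = (~flags).sum(axis=1)
        for i in range(reps):
            keep = ~flags[i]
            if keep.sum() < 3:
                continue
            xs = stats.rankdata(S[i, keep, 0])
            ys = stats.rankdata(S[i, keep, 1])
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue
            r[i] = np.corrcoef(xs, ys)[0, 1]
    else:
        r, m = _batch_pearson(S, ~flags)
    tcrit = skipped_critical_t(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.abs(r) * np.sqrt((m - 2) / (1 - r * r))
    T = np.where(np.abs(r) >= 1, np.inf, T)
    reject = np.isfinite(r) & (T > tcrit) | (np.abs(r) >= 1)
    reject &= ~np.isnan(r)
    return r, reject, int(np.isnan(r).sum())


def _batch_t_reject(r: np.ndarray, n: int, alpha: float = 0.05) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.abs(r) * np.sqrt((n - 2) / (1 - r * r))
    T = np.where(np.abs(r) >= 1, np.inf, T)
    return np.isfinite(r) & (T > stats.t.ppf(1 - alpha / 2, n - 2))


# ---------------------------------------------------------------------------
# the simulation harness


def run_fpr_power(spec: PopulationSpec, methods=("pearson",),
                  n_grid=N_GRID_FULL, n_reps: int = 2000,
                  seed: int | None = None,
                  keep_replicates: bool = False) -> SimulationGridResult:
    """Rejection rate and mean estimate per (n, method) at alpha = 0.05.

    For each n, ``n_reps`` samples are drawn from ``spec`` and every
    method is evaluated on the same draws (paired comparisons).  At
    rho = 0 the rejection rate is the false-positive rate; otherwise it
    is power.  Skipped-method replicates with undefined estimates count
    as non-rejections and are tallied in ``n_undefined``.
    """
    for mth in methods:
        if mth not in _METHODS:
            raise ValueError(f"unknown method '{mth}'")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    root = np.random.SeedSequence(seed)
    rows = []
    reps_store = {}
    for n, ss in zip(n_grid, root.spawn(len(n_grid))):
        rng = np.random.default_rng(ss)
        S = _batch_contaminated(rng, n_reps, n, spec)
        for mth in methods:
            und = 0
            if mth == "pearson":
                r, _ = _batch_pearson(S)
                rej = _batch_t_reject(r, n)
            elif mth == "spearman":
                r = _batch_spearman(S)
                rej = _batch_t_reject(r, n)
            elif mth == "bend":
                r = _batch_bend(S)
                rej = _batch_t_reject(r, n)
            else:
                est = mth.split("-", 1)[1]
                r, rej, und = _batch_skipped(S, rng, estimator=est)
            rows.append({"rho": spec.rho, "n": n, "method": mth,
                         "mean_r": float(np.nanmean(r)),
                         "rejection_rate": float(np.mean(rej)),
                         "n_reps": n_reps, "n_undefined": und})
            if keep_replicates:
                reps_store[(n, mth)] = r
    return SimulationGridResult(pd.DataFrame(rows), reps_store, seed)


def effect_size_bias(result: SimulationGridResult, rho_true: float,
                     n_comparisons: int = len(N_GRID_FULL)) -> pd.DataFrame:
    """Bonferroni-adjusted percentile CI of r - rho per (n, method).

    The 95% level is adjusted for the grid of sample sizes (alpha
    0.05 / n_comparisons, i.e. a 99.9964% CI for the full 14-size grid);
    a method "estimates rho" at that n when 0 lies inside the CI.
    Requires ``run_fpr_power(..., keep_replicates=True)``.
    """
    if not result.replicates:
        raise ValueError("run_fpr_power must be called with keep_replicates=True")
    a = 0.05 / n_comparisons
    rows = []
    for (n, mth), r in result.replicates.items():
        d = r[np.isfinite(r)] - rho_true
        lo, hi = np.percentile(d, [100 * a / 2, 100 * (1 - a / 2)])
        rows.append({"n": n, "method": mth, "ci_lower": lo, "ci_upper": hi,
                     "estimates_rho": bool(lo <= 0 <= hi)})
    return pd.DataFrame(rows)


def compare_methods_median_diff(r_a: np.ndarray, r_b: np.ndarray,
                                n_boot: int = 2000, seed: int | None = None,
                                n_comparisons: int = len(N_GRID_FULL)):
    """Bootstrap CI of the median paired difference between two methods.

    ``r_a`` and ``r_b`` must come from the same draws.  The CI level is
    Bonferroni-adjusted for the sample-size grid; the difference is
    significant when the CI excludes 0.  Returns (lower, upper, h).
    """
    r_a = np.asarray(r_a, float)
    r_b = np.asarray(r_b, float)
    if r_a.shape != r_b.shape:
        raise ValueError("paired replicate arrays must have the same shape")
    d = r_a - r_b
    d = d[np.isfinite(d)]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    med = np.median(d[idx], axis=1)
    a = 0.05 / n_comparisons
    lo, hi = np.percentile(med, [100 * a / 2, 100 * (1 - a / 2)])
    return float(lo), float(hi), int(not (lo <= 0 <= hi))


# ---------------------------------------------------------------------------
# the Schwarzkopf reproduction and the rotating-outlier toy example


def _naive_mcd_removal_reject(S: np.ndarray) -> np.ndarray:
    """The deliberately naive baseline: delete points whose raw MCD robust
    distance (maximal-breakdown coverage, consistency-corrected) exceeds
    sqrt(chi2(0.975, 2)), then apply the UNCORRECTED t-test with m - 2 df.
    """
    reps, n, _ = S.shape
    h = (n + 3) // 2
    subs = _exhaustive_subsets(n, h)
    X = S[:, subs, :]
    mu = X.mean(axis=2)
    C = X - mu[:, :, None, :]
    cov = np.einsum("rmhi,rmhj->rmij", C, C) / (h - 1)
    det = cov[..., 0, 0] * cov[..., 1, 1] - cov[..., 0, 1] ** 2
    best = det.argmin(axis=1)
    ar = np.arange(reps)
    c0 = mu[ar, best]
    cv = cov[ar, best] * _consistency_factor(h / n)
    deti = cv[:, 0, 0] * cv[:, 1, 1] - cv[:, 0, 1] ** 2
    inv = np.empty_like(cv)
    inv[:, 0, 0] = cv[:, 1, 1]
    inv[:, 1, 1] = cv[:, 0, 0]
    inv[:, 0, 1] = -cv[:, 0, 1]
    inv[:, 1, 0] = -cv[:, 1, 0]
    inv /= np.where(deti == 0, 1.0, deti)[:, None, None]
    d = S - c0[:, None, :]
    d2 = np.einsum("rni,rij,rnj->rn", d, inv, d)
    keep = d2 <= _CHI2_975_2
    r, m = _batch_pearson(S, keep)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.abs(r) * np.sqrt((m - 2) / (1 - r * r))
    T = np.where(np.abs(r) >= 1, np.inf, T)
    crit = stats.t.ppf(0.975, np.maximum(m - 2, 1))
    return np.isfinite(r) & (T > crit)


def schwarzkopf_sim(kind: str = "univariate", n_reps: int = 10000,
                    seed: int | None = None,
                    uni_interpretation: str = "variance") -> pd.DataFrame:
    """Type-I-error comparison at n = 10 with one planted outlier.

    Each replicate draws 10 independent standard-normal pairs; one
    randomly chosen observation is replaced by a draw from the outlier
    model: for ``kind="univariate"`` its second coordinate comes from a
    zero-mean normal with variance 3 (``uni_interpretation="sd"`` reads
    the scale as an SD of 3 instead; ``"both"`` contaminates both
    coordinates); for ``kind="bivariate"`` the pair comes from a
    zero-mean bivariate normal with covariance [[3, 4.5], [4.5, 9]].

    Four tests are run at alpha = 0.05 on the same draws: Pearson,
    Pearson after naive MCD-distance removal (uncorrected t-test),
    skipped Pearson with the box-plot rule, and skipped Pearson with the
    MAD-median rule on projections.  Returns a tidy DataFrame of
    rejection rates.
    """
    if kind not in ("univariate", "bivariate", "control"):
        raise ValueError("kind must be 'univariate', 'bivariate' or 'control'")
    n = 10
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((n_reps, n, 2))
    pos = rng.integers(0, n, n_reps)
    ar = np.arange(n_reps)
    if kind == "control":
        pass  # no planted outlier: a nominal-level sanity check
    elif kind == "univariate":
        scale = 3.0 if uni_interpretation == "sd" else np.sqrt(3.0)
        if uni_interpretation == "both":
            S[ar, pos, :] = rng.standard_normal((n_reps, 2)) * np.sqrt(3.0)
        else:
            S[ar, pos, 1] = rng.standard_normal(n_reps) * scale
    else:
        L = np.linalg.cholesky(np.array([[3.0, 4.5], [4.5, 9.0]]))
        S[ar, pos, :] = rng.standard_normal((n_reps, 2)) @ L.T
    r, _ = _batch_pearson(S)
    rows = [{"method": "pearson",
             "type_I": float(np.mean(_batch_t_reject(r, n)))}]
    rows.append({"method": "pearson-mcd-removal",
                 "type_I": float(np.mean(_naive_mcd_removal_reject(S)))})
    for rule, name in (("boxplot", "skipped-boxplot"),
                       ("madmedian", "skipped-madmedian")):
        _, rej, _ = _batch_skipped(S, rng, rule=rule)
        rows.append({"method": name, "type_I": float(np.mean(rej))})
    df = pd.DataFrame(rows)
    df["kind"] = kind
    df["n_reps"] = n_reps
    return df


def rotating_outlier_demo(slope: float = 0.2, angle_deg: float = 80.0):
    """Ten collinear points with the last one rotated off the line.

    The base sample is (x, slope * x) for x = 0..9; the last point is
    replaced by (9, 9 * tan(atan(slope) + angle)), i.e. the endpoint of
    the regression line rotated by ``angle_deg``.  Returns
    ``(x, y, pearson_result, skipped_result)`` — the single outlier can
    reverse Pearson's r while the skipped correlation removes it and
    recovers r = 1 (except for small rotations that stay inside the
    detection cutoff).
    """
    from .correlations import pearson as _pearson, skipped as _skipped
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not 0 <= angle_deg < 180:
        raise ValueError("angle must be in [0, 180)")
    theta = np.arctan(slope) + np.deg2rad(angle_deg)
    if abs(np.cos(theta)) < 1e-12:
        raise ValueError("rotation makes the line vertical")
    x = np.arange(10, dtype=float)
    y = slope * x
    y[-1] = 9 * np.tan(theta)
    return x, y, _pearson(x, y), _skipped(x, y)
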