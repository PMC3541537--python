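"""Robust bivariate location and scatter via the minimum covariance determinant.

The MCD estimator finds the subset of ``h`` points whose covariance matrix
has the smallest determinant; its mean and (consistency-corrected)
covariance are high-breakdown estimates of location and scatter.  The
center anchors the projection-based bivariate outlier detector used by the
skipped correlations, so its breakdown behaviour — not its efficiency —
is what matters downstream.

Two search strategies are used:

* ``n <= 12``: exhaustive enumeration of every size-``h`` subset, which is
  cheap in two dimensions and makes the result seed-independent;
* ``n > 12``: a concentration-step (FAST-MCD style) search seeded from
  random elemental subsets, deterministic for a given ``seed``.

A reweighting step (drop points whose raw robust distance exceeds the
chi-square 0.975 cutoff, then recompute mean and covariance) is applied by
default, following standard FAST-MCD practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["RobustLocationScatter", "mcd_estimate", "mahalanobis_sq"]

_CHI2_975_2 = stats.chi2.ppf(0.975, 2)
_DEGENERATE_DET = 1e-12


@dataclass
class RobustLocationScatter:
    """MCD location/scatter estimate.

    Attributes
    ----------
    center : ndarray, shape (2,)
        Robust location (reweighted unless ``reweight=False`` or degenerate).
    scatter : ndarray, shape (2, 2)
        Symmetric PSD robust scatter matrix, consistency-corrected.
    support_mask : ndarray of bool, shape (n,)
        Indicator of the raw h-subset attaining the minimal determinant.
    h_fraction : float
        Requested coverage fraction in (0.5, 1].
    degenerate : bool
        True when the optimal subset is (numerically) collinear; the
        estimate is still returned but the scatter is singular.
    method : str
        ``"exhaustive"`` or ``"fast"``.
    """

    center: np.ndarray
    scatter: np.ndarray
    support_mask: np.ndarray
    h_fraction: float
    degenerate: bool
    method: str


def _as_points(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return np.column_stack([x, y])


def _h_count(n: int, h_fraction: float) -> int:
    if not 0.5 < h_fraction <= 1.0:
        raise ValueError("h_fraction must be in (0.5, 1]")
    # never below the maximal-breakdown size floor((n + p + 1) / 2), p = 2
    return max(int(np.floor(h_fraction * n)), (n + 3) // 2)


def _consistency_factor(alpha: float, p: int = 2) -> float:
    # asymptotic correction making the h-subset covariance Fisher-consistent
    # at the normal model (Croux & Haesbroeck)
    q = stats.chi2.ppf(alpha, p)
    return alpha / stats.chi2.cdf(q, p + 2)


def _inv2(C: np.ndarray) -> np.ndarray:
    det = C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
    if abs(det) < _DEGENERATE_DET:
        raise np.linalg.LinAlgError("singular 2x2 matrix")
    return np.array([[C[1, 1], -C[0, 1]], [-C[1, 0], C[0, 0]]]) / det


def _exhaustive_raw(P: np.ndarray, h: int):
    """Enumerate all size-h subsets; return (mask, mean, cov, det) of the best."""
    n = len(P)
    subs = np.array(list(combinations(range(n), h)))
    X = P[subs]                              # (m, h, 2)
    mu = X.mean(axis=1)
    C = X - mu[:, None, :]
    cov = np.einsum("mhi,mhj->mij", C, C) / (h - 1)
    det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
    best = int(det.argmin())
    mask = np.zeros(n, dtype=bool)
    mask[subs[best]] = True
    return mask, mu[best], cov[best], float(det[best])


def _cstep_raw(P: np.ndarray, h: int, rng: np.random.Generator,
               n_trials: int = 50, n_keep: int = 10, max_iter: int = 30):
    """FAST-MCD concentration search, vectorised across trials."""
    n = len(P)

    def step(mu, cov):
        # one concentration step for a batch of candidate estimates
        d = P[None, :, :] - mu[:, None, :]
        det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
        det = np.where(np.abs(det) < _DEGENERATE_DET, _DEGENERATE_DET, det)
        inv = np.empty_like(cov)
        inv[:, 0, 0] = cov[:, 1, 1]
        inv[:, 1, 1] = cov[:, 0, 0]
        inv[:, 0, 1] = -cov[:, 0, 1]
        inv[:, 1, 0] = -cov[:, 1, 0]
        inv /= det[:, None, None]
        d2 = np.einsum("tni,tij,tnj->tn", d, inv, d)
        sel = np.argpartition(d2, h - 1, axis=1)[:, :h]
        X = P[sel]
        mu2 = X.mean(axis=1)
        C = X - mu2[:, None, :]
        cov2 = np.einsum("thi,thj->tij", C, C) / (h - 1)
        return sel, mu2, cov2

    # elemental starts: random subsets of size p + 1 = 3
    starts = np.array([rng.choice(n, size=3, replace=False) for _ in range(n_trials)])
    X = P[starts]
    mu = X.mean(axis=1)
    C = X - mu[:, None, :]
    cov = np.einsum("thi,thj->tij", C, C) / 2
    # ridge keeps collinear elemental starts usable; C-steps wash it out
    tr = cov[:, 0, 0] + cov[:, 1, 1]
    cov[:, 0, 0] += 1e-8 * tr + 1e-12
    cov[:, 1, 1] += 1e-8 * tr + 1e-12

    for _ in range(3):
        sel, mu, cov = step(mu, cov)
    det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
    keep = np.argsort(det)[:n_keep]
    sel, mu, cov = sel[keep], mu[keep], cov[keep]
    prev = None
    for _ in range(max_iter):
        sel, mu, cov = step(mu, cov)
        det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
        if prev is not None and np.allclose(det, prev, rtol=1e-12, atol=1e-300):
            break
        prev = det
    best = int(det.argmin())
    mask = np.zeros(n, dtype=bool)
    mask[sel[best]] = True
    return mask, mu[best], cov[best], float(det[best])


def mcd_estimate(x, y, h_fraction: float = 0.75, seed: int | None = None,
                 reweight: bool = True) -> RobustLocationScatter:
    """Minimum covariance determinant location/scatter for paired data.

    Parameters
    ----------
    x, y : array-like
        Paired observations, n >= 5, finite.
    h_fraction : float
        Coverage: the subset size is ``max(floor(h_fraction * n),
        floor((n + 3) / 2))``.  0.75 is the usual default; pass
        ``h_fraction=0.5`` for maximal breakdown.
    seed : int, optional
        Seed for the stochastic search used when n > 12.  Ignored for
        n <= 12, where the search is exhaustive and fully deterministic.
    reweight : bool
        Apply the chi-square(0.975) reweighting step (default).  The raw
        h-subset estimate is returned when False.
    """
    P = _as_points(x, y)
    n = len(P)
    if n < 5:
        raise ValueError("sample too small: MCD needs n >= 5")
    h = _h_count(n, h_fraction)

    if n <= 12:
        mask, mu, cov, det = _exhaustive_raw(P, h)
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        mask, mu, cov, det = _cstep_raw(P, h, rng)
        method = "fast"

    if det < _DEGENERATE_DET:
        return RobustLocationScatter(mu, cov, mask, h_fraction, True, method)

    scatter = cov * _consistency_factor(h / n)
    if not reweight:
        return RobustLocationScatter(mu, scatter, mask, h_fraction, False, method)

    d = P - mu
    d2 = np.einsum("ni,ij,nj->n", d, _inv2(scatter), d)
    w = d2 <= _CHI2_975_2
    if w.sum() < 3:
        # pathological geometry: fall back to the raw estimate
        return RobustLocationScatter(mu, scatter, mask, h_fraction, False, method)
    mu_r = P[w].mean(axis=0)
    cov_r = np.cov(P[w], rowvar=False) * _consistency_factor(0.975)
    det_r = cov_r[0, 0] * cov_r[1, 1] - cov_r[0, 1] ** 2
    if det_r < _DEGENERATE_DET:
        return RobustLocationScatter(mu_r, cov_r, mask, h_fraction, True, method)
    return RobustLocationScatter(mu_r, cov_r, mask, h_fraction, False, method)


def mahalanobis_sq(x, y, est: RobustLocationScatter) -> np.ndarray:
    """Squared Mahalanobis distance of each point from a robust estimate.

    ``d2_i = (p_i - center)' scatter^{-1} (p_i - center)``.
    Raises on a degenerate (singular) scatter.
    """
    P = _as_points(x, y)
    if est.degenerate:
        raise np.linalg.LinAlgError("degenerate scatter: distances undefined")
    inv = _inv2(np.asarray(est.scatter, dtype=float))
    d = P - np.asarray(est.center, dtype=float)
    return np.einsum("ni,ij,nj->n", d, inv, d)
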