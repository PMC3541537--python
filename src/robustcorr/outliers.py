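"""Univariate and projection-based bivariate outlier detection.

Three univariate rules are provided, all gated at the 0.975 normal
quantile scale:

* box-plot rule — median +/- c * IQR, with the interquartile range from
  the ideal-fourths estimator and c either Carling's small-sample constant
  or sqrt(chi2(0.975, 1));
* MAD-median rule — |v - M| / (MAD / 0.6745) > sqrt(chi2(0.975, 1));
* S-outliers — same form with Rousseeuw-Croux Sn as the scale.

Bivariate outliers are found by the projection method: every point is
projected onto the line joining each data point to a robust (MCD) center,
and a point is flagged when the box-plot (or MAD-median) rule flags its
signed projection in any direction.  A point can thus be a bivariate
outlier while unremarkable in both margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .center import mcd_estimate

__all__ = [
    "OutlierReport",
    "ideal_fourths",
    "carling_k",
    "boxplot_outliers",
    "madmedian_outliers",
    "s_outliers",
    "project_distances",
    "bivariate_outliers",
    "detect_outliers",
    "GATE_0975",
]

#: sqrt of the 0.975 chi-square quantile with 1 df (~2.2414); the default
#: gate for the MAD-median, S and projection rules.
GATE_0975 = float(np.sqrt(stats.chi2.ppf(0.975, 1)))


@dataclass
class OutlierReport:
    """Per-point outlier flags for one rule.

    ``flags`` holds the rule's primary output: univariate flags for the
    univariate rules, bivariate flags for the projection detector.
    ``thresholds`` maps names to cutoffs in data units.  ``degenerate``
    is set when the rule's spread estimate collapsed to zero, in which
    case nothing is flagged.
    """

    rule: str
    flags: np.ndarray
    thresholds: dict = field(default_factory=dict)
    gate_constant: float = float("nan")
    degenerate: bool = False

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))


def _check_values(values, min_n: int = 4) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < min_n:
        raise ValueError(f"too few values: need at least {min_n}")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    return v


def ideal_fourths(values) -> tuple[float, float]:
    """Ideal-fourths (interpolated) estimate of the lower and upper quartiles.

    With sorted values x_(1) <= ... <= x_(n), j = floor(n/4 + 5/12) and
    g = n/4 + 5/12 - j, the lower fourth is (1-g) x_(j) + g x_(j+1); the
    upper fourth is taken symmetrically from the top.
    """
    v = _check_values(values)
    n = len(v)
    s = np.sort(v)
    j = int(np.floor(n / 4 + 5 / 12))
    g = n / 4 + 5 / 12 - j
    q1 = (1 - g) * s[j - 1] + g * s[j]
    q3 = (1 - g) * s[n - j] + g * s[n - j - 1]
    return float(q1), float(q3)


def carling_k(n: int) -> float:
    """Carling's sample-size-adjusted box-plot constant.

    k = (17.63 n - 23.64) / (7.74 n - 3.71); tends to ~2.278 as n grows.
    """
    if n < 4:
        raise ValueError("too few values: need at least 4")
    return (17.63 * n - 23.64) / (7.74 * n - 3.71)


def boxplot_outliers(values, variant: str = "carling") -> OutlierReport:
    """Box-plot rule: flag v outside median +/- c * IQR(ideal fourths).

    ``variant="carling"`` uses Carling's k(n); ``variant="chi_gate"`` uses
    sqrt(chi2(0.975, 1)).
    """
    v = _check_values(values)
    if variant == "carling":
        c = carling_k(len(v))
    elif variant == "chi_gate":
        c = GATE_0975
    else:
        raise ValueError("variant must be 'carling' or 'chi_gate'")
    m = float(np.median(v))
    q1, q3 = ideal_fourths(v)
    iqr = q3 - q1
    if iqr <= 0:
        return OutlierReport("boxplot", np.zeros(len(v), bool),
                             {"median": m, "q1": q1, "q3": q3},
                             c, degenerate=True)
    lo, hi = m - c * iqr, m + c * iqr
    return OutlierReport("boxplot", (v < lo) | (v > hi),
                         {"median": m, "q1": q1, "q3": q3,
                          "lower": lo, "upper": hi}, c)


def madmedian_outliers(values) -> OutlierReport:
    """MAD-median rule: |v - M| / (MAD / 0.6745) > sqrt(chi2(0.975, 1))."""
    v = _check_values(values)
    m = float(np.median(v))
    madn = float(np.median(np.abs(v - m))) / 0.6745
    if madn <= 0:
        return OutlierReport("madmedian", np.zeros(len(v), bool),
                             {"median": m, "madn": 0.0},
                             GATE_0975, degenerate=True)
    flags = np.abs(v - m) / madn > GATE_0975
    return OutlierReport("madmedian", flags,
                         {"median": m, "madn": madn,
                          "lower": m - GATE_0975 * madn,
                          "upper": m + GATE_0975 * madn}, GATE_0975)


def _sn_scale(v: np.ndarray) -> float:
    # Rousseeuw-Croux Sn = 1.1926 * med_i med_j |v_i - v_j|
    diffs = np.abs(v[:, None] - v[None, :])
    return 1.1926 * float(np.median(np.median(diffs, axis=1)))


def s_outliers(values) -> OutlierReport:
    """S-outlier rule: |v - M| / Sn > sqrt(chi2(0.975, 1))."""
    v = _check_values(values)
    m = float(np.median(v))
    sn = _sn_scale(v)
    if sn <= 0:
        return OutlierReport("s", np.zeros(len(v), bool),
                             {"median": m, "sn": 0.0},
                             GATE_0975, degenerate=True)
    flags = np.abs(v - m) / sn > GATE_0975
    return OutlierReport("s", flags,
                         {"median": m, "sn": sn,
                          "lower": m - GATE_0975 * sn,
                          "upper": m + GATE_0975 * sn}, GATE_0975)


def project_distances(x, y, center, signed: bool = False) -> np.ndarray:
    """Projections of all points onto the rays center -> point i.

    Row i holds, for every point j, the scalar projection of p_j - center
    onto the unit vector toward p_i.  With ``signed=False`` (default) the
    magnitudes |w_j| * ||B_i|| are returned; ``signed=True`` keeps the sign
    of the projection coefficient, which the bivariate detector uses so
    that points on opposite sides of the center are judged against a
    two-sided cutoff.  Rows whose direction point coincides with the
    center are zero.
    """
    P = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    c = np.asarray(center, dtype=float)
    C = P - c
    G = C @ C.T
    norms = np.sqrt((C ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        D = G / norms[:, None]
    D[norms == 0] = 0.0
    return D if signed else np.abs(D)


def _rowwise_ideal_fourths(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = D.shape[-1]
    s = np.sort(D, axis=-1)
    j = int(np.floor(n / 4 + 5 / 12))
    g = n / 4 + 5 / 12 - j
    q1 = (1 - g) * s[..., j - 1] + g * s[..., j]
    q3 = (1 - g) * s[..., n - j] + g * s[..., n - j - 1]
    return q1, q3


def _projection_flags(D: np.ndarray, rule: str, gate: float):
    """Two-sided per-direction cutoffs on signed projections; any-direction OR."""
    M = np.median(D, axis=-1)
    if rule == "boxplot":
        q1, q3 = _rowwise_ideal_fourths(D)
        spread = q3 - q1
    elif rule == "madmedian":
        spread = np.median(np.abs(D - M[..., None]), axis=-1) / 0.6745
    else:
        raise ValueError("rule must be 'boxplot' or 'madmedian'")
    valid = spread > 0
    hi = M + gate * spread
    lo = M - gate * spread
    out = ((D > hi[..., None]) | (D < lo[..., None])) & valid[..., None]
    return out.any(axis=-2), lo, hi, valid


def bivariate_outliers(x, y, rule: str = "boxplot", gate: float | None = None,
                       h_fraction: float = 0.75, seed: int | None = None,
                       center=None) -> OutlierReport:
    """Projection-based bivariate outlier detection.

    Points are projected onto the line joining each observation to the
    MCD center; a point is an outlier when, in any direction, its signed
    projection falls outside median +/- gate * spread of that direction's
    projections (spread = ideal-fourths IQR for ``rule="boxplot"``,
    normalised MAD for ``rule="madmedian"``).  The default gate is
    sqrt(chi2(0.975, 1)).

    ``center`` may be supplied to bypass the MCD (mainly for testing).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 5:
        raise ValueError("too few values: need at least 5")
    if gate is None:
        gate = GATE_0975
    if center is None:
        center = mcd_estimate(xa, ya, h_fraction=h_fraction, seed=seed).center
    D = project_distances(xa, ya, center, signed=True)
    flags, lo, hi, valid = _projection_flags(D, rule, gate)
    return OutlierReport(f"projection-{rule}", flags,
                         {"center": np.asarray(center, float),
                          "lower": lo, "upper": hi,
                          "valid_directions": valid}, gate)


def detect_outliers(x, y, h_fraction: float = 0.75,
                    seed: int | None = None) -> dict:
    """Run all univariate rules on each margin plus the projection detector.

    Returns a dict with keys ``boxplot``, ``madmedian``, ``s`` (each a pair
    of marginal reports) and ``bivariate``.
    """
    out = {}
    for name, fn in (("boxplot", boxplot_outliers),
                     ("madmedian", madmedian_outliers),
                     ("s", s_outliers)):
        out[name] = {"x": fn(x), "y": fn(y)}
    out["bivariate"] = bivariate_outliers(x, y, h_fraction=h_fraction, seed=seed)
    return out
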