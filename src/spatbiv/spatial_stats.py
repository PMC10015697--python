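"""Zone- and point-level spatial statistics.

Global Moran's I under binary adjacency weights (normal-approximation
inference under the randomization assumption, or Monte-Carlo permutation),
Getis-Ord Gi* hotspot scores, the autologistic neighbor-average autocovariate,
and ordinary kriging with Matheron semivariogram estimation and weighted
least-squares model fitting.

All estimators take the package's :class:`~spatbiv.core_io.SpatialWeights`
(symmetric 0/1, zero diagonal) or planar :class:`~spatbiv.core_io.PointSample`
sequences; distances are Euclidean throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist, pdist, squareform

from .core_io import PointSample, SpatialWeights, ValidationError

VariogramModel = Literal["spherical", "exponential", "gaussian"]


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z_score: float
    p_value: float
    method: str
    n: int
    n_permutations: int | None = None
    seed: int | None = None


def _moran_statistic(z: np.ndarray, w: np.ndarray) -> float:
    # z is already mean-centred
    n = len(z)
    s0 = w.sum()
    return float(n * (z @ w @ z) / (s0 * (z @ z)))


def morans_i(
    values: Sequence[float],
    W: SpatialWeights,
    method: Literal["normal", "permutation"] = "normal",
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I of per-zone values under binary adjacency weights.

    I = n * sum_ij w_ij (y_i - ybar)(y_j - ybar) / (S0 * sum_i (y_i - ybar)^2).

    Inference defaults to the closed-form normal approximation under the
    randomization assumption; ``method="permutation"`` instead permutes the
    values over zones ``n_permutations`` times with the given seed and reports
    the one-sided tail probability in the direction of the observed deviation
    from E[I] = -1/(n-1). Zones without neighbors are excluded with a warning.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != W.n_zones:
        raise ValidationError("values length must match the number of zones")
    keep = np.array([W.degree(z) > 0 for z in W.zone_order])
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} island zone(s) from Moran's I", stacklevel=2
        )
    y = y[keep]
    w = W.to_dense()[np.ix_(keep, keep)]
    n = len(y)
    if n < 3:
        raise ValidationError("Moran's I needs at least 3 connected zones")
    z = y - y.mean()
    if np.allclose(z, 0):
        raise ValidationError("zero variance, Moran's I undefined")
    I = _moran_statistic(z, w)
    e_i = -1.0 / (n - 1)

    if method == "normal":
        if n < 4:
            raise ValidationError(
                "the randomization variance needs >= 4 connected zones; use method='permutation'"
            )
        s0 = w.sum()
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
        b2 = n * (z**4).sum() / (z**2).sum() ** 2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        var = num / den - e_i**2
        zsc = (I - e_i) / np.sqrt(var)
        p = float(stats.norm.sf(abs(zsc)))
        return MoranResult(I, e_i, float(var), float(zsc), p, "normal-approximation", n)

    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    sims = np.empty(n_permutations)
    for k in range(n_permutations):
        zp = rng.permutation(z)
        sims[k] = _moran_statistic(zp, w)
    if I >= e_i:
        extreme = int((sims >= I).sum())
    else:
        extreme = int((sims <= I).sum())
    p = (1.0 + extreme) / (1.0 + n_permutations)
    var = float(sims.var(ddof=0))
    zsc = (I - e_i) / np.sqrt(var) if var > 0 else np.inf
    return MoranResult(I, e_i, var, float(zsc), float(p), "permutation", n, n_permutations, seed)


# ---------------------------------------------------------------------------
# Getis-Ord Gi*
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GiStarResult:
    zones: list[str]
    z_scores: np.ndarray
    p_values: np.ndarray
    hotspot: np.ndarray  # +1 hot, -1 cold, 0 neither, at level alpha
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": self.zones,
                "gi_star_z": self.z_scores,
                "p_value": self.p_values,
                "hotspot": self.hotspot,
            }
        )


def gi_star(values: Sequence[float], W: SpatialWeights, alpha: float = 0.05) -> GiStarResult:
    """Getis-Ord Gi* hotspot z-score per zone, with self-inclusion and binary weights.

    A zone is flagged hot (+1) when its z-score exceeds the upper alpha/2
    normal quantile — a high value surrounded by high values — and cold (-1)
    symmetrically. Constant input yields all-zero scores with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != W.n_zones:
        raise ValidationError("values length must match the number of zones")
    n = len(x)
    if n < 3:
        raise ValidationError("Gi* needs at least 3 zones")
    w = W.to_dense() + np.eye(n)  # Gi* includes the zone itself
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    crit = stats.norm.ppf(1 - alpha / 2)
    if s == 0:
        warnings.warn("constant values: all Gi* scores set to 0", stacklevel=2)
        z = np.zeros(n)
    else:
        wsum = w.sum(axis=1)
        w2sum = (w**2).sum(axis=1)
        num = w @ x - xbar * wsum
        den = s * np.sqrt((n * w2sum - wsum**2) / (n - 1))
        z = num / den
    p = 2 * stats.norm.sf(np.abs(z))
    flags = np.where(z > crit, 1, np.where(z < -crit, -1, 0))
    return GiStarResult(list(W.zone_order), z, p, flags, alpha)


# ---------------------------------------------------------------------------
# autologistic autocovariate
# ---------------------------------------------------------------------------

def autocovariate(y: Sequence[float], W: SpatialWeights) -> np.ndarray:
    """Neighbor-average autocovariate S_i = sum_j w_ij y_j / sum_j w_ij.

    With binary weights this is the plain mean of the neighbors' values; a
    zone with no neighbors falls back to the global mean with a warning.
    """
    yv = np.asarray(y, dtype=float)
    if len(yv) != W.n_zones:
        raise ValidationError("values length must match the number of zones")
    w = W.to_dense()
    deg = w.sum(axis=1)
    s = np.empty(len(yv))
    islands = deg == 0
    if islands.any():
        warnings.warn(
            f"{int(islands.sum())} island zone(s): autocovariate set to the global mean",
            stacklevel=2,
        )
        s[islands] = yv.mean()
    nz = ~islands
    s[nz] = (w @ yv)[nz] / deg[nz]
    return s


# ---------------------------------------------------------------------------
# semivariogram + ordinary kriging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variogram:
    """Isotropic semivariogram: gamma(0)=nugget, rising to nugget+partial_sill at the range."""

    model: VariogramModel
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValidationError("variogram needs nugget>=0, partial_sill>=0, range>0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a, c0, c = self.range_, self.nugget, self.partial_sill
        if self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            struct = c * (1.5 * hr - 0.5 * hr**3)
        elif self.model == "exponential":
            struct = c * (1.0 - np.exp(-3.0 * h / a))
        elif self.model == "gaussian":
            struct = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        else:  # pragma: no cover - guarded by the Literal type
            raise ValueError(f"unknown model {self.model!r}")
        out = np.where(h > 0, c0 + struct, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class KrigingPrediction:
    location: tuple[float, float]
    value: float
    variance: float
    weights: np.ndarray = field(repr=False)


def empirical_semivariogram(
    points: Sequence[PointSample], n_bins: int = 10, max_dist: float | None = None
) -> pd.DataFrame:
    """Matheron estimator gamma(h) = (1/2N(h)) sum (Z_i - Z_j)^2 in equal-width lag bins.

    ``max_dist`` defaults to half the maximum pairwise distance; empty bins
    are omitted. Returns columns ``lag`` (bin centre), ``gamma``, ``n_pairs``.
    """
    if len(points) < 2:
        raise ValidationError("need at least 2 points for a semivariogram")
    xy = np.array([(p.x, p.y) for p in points])
    z = np.array([p.value for p in points])
    d = pdist(xy)
    sq = 0.5 * pdist(z[:, None], metric="sqeuclidean")
    if max_dist is None:
        max_dist = float(d.max()) / 2.0 if d.max() > 0 else 1.0
    if max_dist <= 0:
        raise ValidationError("max_dist must be positive")
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d > lo) & (d <= hi) if lo > 0 else (d > 0) & (d <= hi)
        if mask.any():
            rows.append(((lo + hi) / 2.0, float(sq[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def fit_variogram(empirical: pd.DataFrame, model: VariogramModel = "spherical") -> Variogram:
    """Weighted least-squares fit of (nugget, partial sill, range) to an empirical table.

    Weights are the per-bin pair counts; nonnegativity is enforced by bounded
    optimization. Needs at least 3 nonempty bins.
    """
    if len(empirical) < 3:
        raise ValidationError("need at least 3 nonempty bins to fit a variogram")
    h = empirical["lag"].to_numpy(float)
    g = empirical["gamma"].to_numpy(float)
    npairs = empirical["n_pairs"].to_numpy(float)
    w = np.sqrt(npairs)

    def resid(theta):
        c0, c, a = theta
        return w * (Variogram(model, c0, c, a)(h) - g)

    sill0 = max(g.max(), 1e-12)
    x0 = np.array([min(g[0], sill0) * 0.5, sill0, max(h.max() * 0.5, 1e-6)])
    # range capped at 3x the largest lag: beyond that the models are not
    # identifiable from the observed lags and the fit degenerates
    res = optimize.least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, 3.0 * h.max()]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"variogram fit failed: {res.message} (theta={res.x})")
    c0, c, a = res.x
    return Variogram(model, float(c0), float(c), float(max(a, 1e-12)))


def ordinary_kriging(
    points: Sequence[PointSample],
    vgm: Variogram,
    targets: Sequence[tuple[float, float]],
) -> list[KrigingPrediction]:
    """Ordinary-kriging predictions Z(s0) = sum_i lambda_i Z(s_i) at each target.

    Solves the semivariance system augmented with the unbiasedness constraint
    (sum of weights = 1 via a Lagrange multiplier). With a zero nugget the
    interpolator is exact at data locations with zero kriging variance.
    """
    if len(points) < 2:
        raise ValidationError("need at least 2 data points for kriging")
    xy = np.array([(p.x, p.y) for p in points])
    z = np.array([p.value for p in points])
    n = len(points)
    gamma_dd = vgm(squareform(pdist(xy)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_dd
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        a_fac = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular kriging matrix: check for duplicate data locations and deduplicate"
        ) from exc
    tg = np.atleast_2d(np.asarray(targets, dtype=float))
    gamma_d0 = vgm(cdist(xy, tg))
    out = []
    for j, s0 in enumerate(tg):
        b = np.append(gamma_d0[:, j], 1.0)
        sol = a_fac @ b
        lam, mu = sol[:n], sol[n]
        var = float(lam @ gamma_d0[:, j] + mu)
        out.append(
            KrigingPrediction(
                location=(float(s0[0]), float(s0[1])),
                value=float(lam @ z),
                variance=max(var, 0.0),
                weights=lam,
            )
        )
    return out
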