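"""Semivariogram range estimation and Getis-Ord local Gi* hotspot detection.

The neighborhood (distance band) for the local Gi* statistic is derived from
the data itself: an empirical semivariogram is fitted with a bounded
variogram model and its range — the distance beyond which values are
effectively uncorrelated — becomes the band distance. Points whose
band-neighborhood mean is significantly above (below) the pelt-wide mean at
|z| >= 1.96 are labelled hot (cold); the raw z is thresholded with no
multiple-testing correction, matching common practice in local-cluster maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

from .pelt_model import PeltGrid

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.96


class SpatialError(ValueError):
    pass


@dataclass
class VariogramModel:
    """Empirical semivariogram plus a fitted bounded model."""

    lags: np.ndarray           # bin-centre distances
    gamma: np.ndarray          # semivariances, (µg/g)^2
    pair_counts: np.ndarray
    model: str                 # "spherical" | "exponential"
    nugget: float
    sill: float
    range_: float              # canonical units; feeds the Gi* band
    fallback: bool = False     # True when range = max lag / 2 was imposed

    def __post_init__(self) -> None:
        if self.range_ <= 0:
            raise SpatialError("variogram range must be > 0")
        if self.nugget < 0 or self.sill < self.nugget:
            raise SpatialError("need 0 <= nugget <= sill")


@dataclass
class GiStarField:
    """Standardized local Gi* scores and hot/cold/neutral labels."""

    z: np.ndarray
    labels: np.ndarray         # "hot" | "cold" | "neutral"
    band_distance: float
    threshold: float = DEFAULT_THRESHOLD


def _spherical(h, nugget, psill, rng):
    hr = np.minimum(h / rng, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr ** 3)


def _exponential(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-3.0 * h / rng))


_MODELS = {"spherical": _spherical, "exponential": _exponential}


def default_n_bins(n_points: int) -> int:
    """ceil(sqrt(number of pairs)), capped at 15."""
    n_pairs = n_points * (n_points - 1) // 2
    return min(15, int(np.ceil(np.sqrt(n_pairs))))


def empirical_semivariogram(points: np.ndarray, values: np.ndarray,
                            n_bins: int | None = None,
                            cutoff: float | None = None):
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N_h) per lag bin.

    Bins partition (0, cutoff] evenly, where cutoff defaults to the maximum
    pairwise distance; empty bins are dropped. Pairs beyond the cutoff are
    excluded — long-lag estimates rest on few pairs and are unreliable, so
    pipeline callers cap the cutoff at a third of the point-cloud diagonal
    (the gstat convention). Returns (lag bin centres, gamma, pair counts).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise SpatialError("need >= 2 points")
    d = pdist(points)
    if np.all(d == 0):
        raise SpatialError("all points coincident: no nonzero lags")
    if n_bins is None:
        n_bins = default_n_bins(len(points))
    if n_bins < 1:
        raise SpatialError("n_bins must be >= 1")
    if cutoff is None:
        cutoff = float(d.max())
    if cutoff <= 0:
        raise SpatialError("cutoff must be > 0")
    sqdiff = pdist(values[:, None], metric="sqeuclidean")
    keep = d <= cutoff
    d, sqdiff = d[keep], sqdiff[keep]
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    # right-closed bins over (0, dmax]; zero-distance pairs are excluded
    idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
    idx[d == 0] = -1
    lags, gamma, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        n_h = int(m.sum())
        if n_h == 0:
            continue
        lags.append(0.5 * (edges[b] + edges[b + 1]))
        gamma.append(sqdiff[m].sum() / (2.0 * n_h))
        counts.append(n_h)
    return np.array(lags), np.array(gamma), np.array(counts, dtype=int)


def fit_variogram_range(lags, gamma, pair_counts,
                        model: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a bounded variogram model.

    Weights are the per-bin pair counts. If the optimizer fails, or the
    fitted range exceeds the maximum lag, the range falls back to half the
    maximum pairwise distance and the result is flagged.
    """
    lags = np.asarray(lags, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    pair_counts = np.asarray(pair_counts, dtype=float)
    if model not in _MODELS:
        raise SpatialError(f"unknown variogram model {model!r}")
    if len(lags) < 3:
        raise SpatialError("need >= 3 nonempty bins; use the fallback range")
    order = np.argsort(lags)
    lags, gamma, pair_counts = lags[order], gamma[order], pair_counts[order]
    fn = _MODELS[model]
    max_lag = float(lags.max())
    sill0 = max(float(gamma.mean()), 1e-12)
    p0 = (0.0, sill0, max_lag / 2)
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                fn, lags, gamma, p0=p0,
                sigma=1.0 / np.sqrt(pair_counts),
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 10 * max_lag]),
                maxfev=20000,
            )
        nugget, psill, rng_ = float(popt[0]), float(popt[1]), float(popt[2])
    except (RuntimeError, ValueError):
        nugget, psill, rng_ = 0.0, sill0, max_lag / 2
        fallback = True
    # pure-nugget fit leaves the range unidentified
    if psill <= 1e-10 * max(nugget, sill0):
        rng_ = max_lag / 2
        fallback = True
    if rng_ > max_lag or not np.isfinite(rng_):
        rng_ = max_lag / 2
        fallback = True
    if fallback:
        logger.info("variogram range fell back to max lag / 2 = %.4g", rng_)
    return VariogramModel(lags=lags, gamma=gamma,
                          pair_counts=pair_counts.astype(int), model=model,
                          nugget=nugget, sill=nugget + psill, range_=rng_,
                          fallback=fallback)


def gi_star(points: np.ndarray, values: np.ndarray, band_distance: float,
            threshold: float = DEFAULT_THRESHOLD) -> GiStarField:
    """Getis-Ord local Gi* with binary distance-band weights.

    The focal point is included in its own neighborhood (the "star" variant)
    and ties at exactly the band distance are neighbors. For point i with
    weights w_ij = 1[d(i,j) <= band]:

        z_i = (sum_j w_ij x_j - xbar W_i)
              / (s * sqrt((n sum_j w_ij^2 - W_i^2) / (n - 1)))

    with xbar and s the mean and population (n-denominator) sd over all n
    points. A constant field leaves the statistic undefined: scores are NaN
    and every label neutral, with a warning.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(points)
    if n < 3:
        raise SpatialError("need >= 3 points")
    if band_distance <= 0:
        raise SpatialError("band_distance must be > 0")
    xbar = values.mean()
    s = values.std()  # population sd
    if s <= 1e-12 * max(1.0, abs(xbar)):  # constant up to rounding
        warnings.warn("constant field: Gi* undefined, all labels neutral",
                      RuntimeWarning, stacklevel=2)
        return GiStarField(z=np.full(n, np.nan),
                           labels=np.full(n, "neutral", dtype=object),
                           band_distance=band_distance, threshold=threshold)
    d = squareform(pdist(points))
    w = (d <= band_distance).astype(float)  # diagonal included: d_ii = 0
    wi = w.sum(axis=1)
    num = w @ values - xbar * wi
    denom = s * np.sqrt((n * (w ** 2).sum(axis=1) - wi ** 2) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, num / denom, 0.0)
    labels = np.where(z >= threshold, "hot",
                      np.where(z <= -threshold, "cold", "neutral")).astype(object)
    return GiStarField(z=z, labels=labels, band_distance=band_distance,
                       threshold=threshold)


def derive_band(coords: np.ndarray, values: np.ndarray,
                n_bins: int | None = None,
                model: str = "spherical") -> VariogramModel:
    """Variogram-derived neighborhood for arbitrary point data.

    Estimates the semivariogram up to a third of the point-cloud diagonal and
    fits `model`; if fewer than 3 bins are available the range falls back to
    half the maximum pairwise distance, flagged.
    """
    cutoff = float(pdist(coords).max()) / 3
    lags, gamma, counts = empirical_semivariogram(coords, values, n_bins,
                                                  cutoff=cutoff)
    try:
        return fit_variogram_range(lags, gamma, counts, model=model)
    except SpatialError:
        half = float(pdist(coords).max()) / 2
        return VariogramModel(lags=lags, gamma=gamma, pair_counts=counts,
                              model=model, nugget=0.0,
                              sill=max(float(np.var(values)), 1e-12),
                              range_=half, fallback=True)


def hotspot_map(grid: PeltGrid, value_field: str = "thg",
                n_bins: int | None = None, model: str = "spherical",
                threshold: float = DEFAULT_THRESHOLD
                ) -> tuple[GiStarField, VariogramModel]:
    """Semivariogram -> fitted range -> Gi* for one pelt layer.

    The semivariogram is estimated up to a third of the point-cloud diagonal
    (the gstat default cutoff) and its fitted range becomes the Gi* band.
    Returns the Gi* field (its band_distance records the range used) and the
    fitted variogram.
    """
    coords = grid.coords
    values = grid.values(value_field)
    vg = derive_band(coords, values, n_bins, model=model)
    gi = gi_star(coords, values, band_distance=vg.range_, threshold=threshold)
    return gi, vg
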