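"""Synthetic landscapes with known, controllable structure.

The generators emulate the statistical shape of real inputs — spatially
autocorrelated fractional greenspace fields with a set coverage rate,
clustered population-count surfaces whose coupling to greenspace can be
dialed from strongly negative to strongly positive, four-season greenspace
stacks with a deciduous phenology amplitude, and multi-city covariate tables
with planted linear effects on the exposure Gini — so that every downstream
statistic can be tested against ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .grid_io import Grid

__all__ = [
    "LandscapeParams",
    "SeasonalParams",
    "CityCollectionParams",
    "COVARIATE_NAMES",
    "gen_gaussian_field",
    "gen_greenspace",
    "gen_population",
    "gen_seasonal_stack",
    "gen_city_collection",
]

log = logging.getLogger(__name__)

#: The 16 city-level candidate drivers of exposure inequality, spanning
#: geography, topography, climate, socioeconomics and greenspace landscape.
COVARIATE_NAMES = [
    "lat", "lon", "elevation", "slope",
    "prcp", "temp", "vpd",
    "ntl", "pop_density", "road_length",
    "gcr", "mean_patch_size", "largest_patch_size",
    "pa_ratio", "shape_index", "ed",
]

# Loosely realistic (mean, sd) pairs used when no distribution is supplied.
_DEFAULT_COV_DISTS = {
    "lat": (30.0, 20.0), "lon": (10.0, 60.0),
    "elevation": (300.0, 250.0), "slope": (3.0, 2.0),
    "prcp": (80.0, 40.0), "temp": (15.0, 8.0), "vpd": (0.8, 0.4),
    "ntl": (20.0, 10.0), "pop_density": (3000.0, 1500.0),
    "road_length": (8.0, 4.0),
    "gcr": (0.35, 0.15), "mean_patch_size": (5e4, 2e4),
    "largest_patch_size": (5e5, 2e5), "pa_ratio": (0.05, 0.02),
    "shape_index": (1.5, 0.3), "ed": (120.0, 50.0),
}


@dataclass
class LandscapeParams:
    """Controls one synthetic greenspace/population landscape."""

    shape: tuple[int, int] = (128, 128)
    cell_size: float = 100.0
    correlation_length: float = 500.0
    target_coverage: float = 0.35
    pop_total: int = 100_000
    pop_clustering: float = 1.0
    pop_green_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_coverage <= 1.0:
            raise ValueError("target_coverage must lie in [0, 1]")
        if self.pop_total < 0:
            raise ValueError("pop_total must be >= 0")
        if not self.correlation_length > 0:
            raise ValueError("correlation_length must be positive")
        if not -1.0 <= self.pop_green_corr <= 1.0:
            raise ValueError("pop_green_corr must lie in [-1, 1]")
        if self.pop_clustering < 0:
            raise ValueError("pop_clustering must be >= 0")


@dataclass
class SeasonalParams:
    """Phenology knobs for the four-season greenspace stack."""

    deciduous_fraction: float = 0.5
    winter_retention: float = 0.2
    shoulder_retention: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deciduous_fraction", "winter_retention",
                     "shoulder_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CityCollectionParams:
    """Controls the multi-city driver table with a planted linear response."""

    n_cities: int = 100
    covariate_dists: dict = field(default_factory=dict)
    planted_coefficients: dict = field(default_factory=dict)
    intercept: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 3:
            raise ValueError("n_cities must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.planted_coefficients) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariates in planted_coefficients: "
                             f"{sorted(unknown)}")


def gen_gaussian_field(
    shape: tuple[int, int],
    correlation_length: float,
    cell_size: float,
    seed: int,
) -> np.ndarray:
    """Sample-standardized Gaussian random field.

    White noise is smoothed with a Gaussian kernel of scale
    ``correlation_length`` (in meters, converted to cells) using wrapped
    boundaries so the field is stationary, then standardized to exactly
    zero sample mean and unit sample variance.
    """
    if correlation_length < cell_size:
        raise ValueError("correlation_length must be >= cell_size")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma = correlation_length / cell_size
    fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    fld = fld - fld.mean()
    sd = fld.std()
    if sd > 0:
        fld = fld / sd
    return fld


def _coverage_transform(u: np.ndarray, target: float) -> np.ndarray:
    """Monotone map of uniform scores to [0,1] fractions with exact mean.

    Applies the power transform u**theta, with theta solved so the sample
    mean equals ``target``; theta -> 0 pushes the mean to 1, theta -> inf
    pushes it to 0, and the mean is strictly monotone in theta, so a 1-D
    root find lands the mean within floating error.
    """
    if target <= 0.0:
        return np.zeros_like(u)
    if target >= 1.0:
        return np.ones_like(u)

    def mean_err(log_theta: float) -> float:
        return float(np.mean(u ** np.exp(log_theta))) - target

    log_theta = optimize.brentq(mean_err, -30.0, 30.0, xtol=1e-14)
    return u ** np.exp(log_theta)


def gen_greenspace(params: LandscapeParams) -> Grid:
    """Spatially autocorrelated fractional greenspace grid.

    A Gaussian field is pushed through the normal CDF (rank-preserving,
    giving uniform scores) and then through an exact mean-correcting
    monotone power transform, so the realized mean coverage over valid
    cells matches ``target_coverage`` to floating precision.
    """
    fld = gen_gaussian_field(
        params.shape, params.correlation_length, params.cell_size, params.seed
    )
    u = stats.norm.cdf(fld)
    values = _coverage_transform(u, params.target_coverage)
    log.debug("gen_greenspace: seed=%d target=%.4f realized=%.6f",
              params.seed, params.target_coverage, values.mean())
    return Grid(values=values, cell_size=params.cell_size)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerize ``total * weights`` (weights sum to 1) with exact total."""
    raw = weights * total
    base = np.floor(raw).astype(np.int64)
    shortfall = int(total - base.sum())
    if shortfall > 0:
        remainders = raw - base
        # ties broken by cell index (stable argsort of negated remainders)
        order = np.argsort(-remainders, kind="stable")
        base[order[:shortfall]] += 1
    return base


def gen_population(params: LandscapeParams, greenspace: Grid) -> Grid:
    """Clustered population counts, optionally coupled to greenspace.

    The log-intensity is ``pop_clustering`` times a standardized mixture of
    the (standardized) greenspace fraction and an independent Gaussian
    field, mixed so its correlation with greenspace has the sign and rough
    magnitude of ``pop_green_corr``. Counts are allocated by largest
    remainder, so the total over valid cells equals ``pop_total`` exactly.
    """
    if greenspace.shape != tuple(params.shape):
        raise ValueError("greenspace grid shape does not match params.shape")
    rng_seed = params.seed + 1_000_003  # decouple from the greenspace draw
    indep = gen_gaussian_field(
        params.shape, params.correlation_length, params.cell_size, rng_seed
    )
    g = greenspace.values
    g_sd = g.std()
    g_std = (g - g.mean()) / g_sd if g_sd > 0 else np.zeros_like(g)
    rho = params.pop_green_corr
    z = rho * g_std + np.sqrt(max(0.0, 1.0 - rho**2)) * indep
    intensity = np.exp(params.pop_clustering * z)
    intensity[greenspace.nodata_mask] = 0.0
    total_intensity = intensity.sum()
    if total_intensity <= 0:
        raise ValueError("degenerate population intensity field")
    weights = intensity / total_intensity
    counts = _largest_remainder(weights.ravel(), int(params.pop_total))
    values = counts.reshape(params.shape).astype(float)
    return Grid(
        values=values,
        cell_size=params.cell_size,
        origin=greenspace.origin,
        nodata_mask=greenspace.nodata_mask.copy(),
        crs_epsg=greenspace.crs_epsg,
    )


def gen_seasonal_stack(base: Grid, params: SeasonalParams) -> dict[str, Grid]:
    """Four-season greenspace stack around a summer baseline.

    A seeded per-cell draw marks a ``deciduous_fraction`` subset of green
    cells as deciduous; those cells keep ``winter_retention`` of their
    summer greenness in winter and ``shoulder_retention`` in spring and
    autumn. Evergreen cells are unchanged in every season.
    """
    rng = np.random.default_rng(params.seed)
    deciduous = (rng.random(base.shape) < params.deciduous_fraction) & (
        base.values > 0
    )

    def scaled(retention: float) -> Grid:
        vals = base.values.copy()
        vals[deciduous] *= retention
        return Grid(
            values=np.clip(vals, 0.0, 1.0),
            cell_size=base.cell_size,
            origin=base.origin,
            nodata_mask=base.nodata_mask.copy(),
            crs_epsg=base.crs_epsg,
        )

    return {
        "spring": scaled(params.shoulder_retention),
        "summer": scaled(1.0),
        "autumn": scaled(params.shoulder_retention),
        "winter": scaled(params.winter_retention),
    }


def gen_city_collection(
    params: CityCollectionParams,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Multi-city driver table with a planted linear Gini response.

    Covariates are drawn i.i.d. normal per city from per-covariate
    (mean, sd) settings; the response is the planted linear combination of
    the min–max rescaled covariates plus the intercept and Gaussian noise,
    clipped to [0, 1]. Returns the table (raw-scale covariates plus a
    ``gini`` column) and the generative coefficients on the rescaled scale.
    Rows clipped are counted in the log; recovery tests should use regimes
    where clipping is rare.
    """
    rng = np.random.default_rng(params.seed)
    dists = {**_DEFAULT_COV_DISTS, **params.covariate_dists}
    data = {}
    for name in COVARIATE_NAMES:
        mu, sd = dists[name]
        data[name] = rng.normal(mu, sd, size=params.n_cities)
    df = pd.DataFrame(data)

    scaled = (df - df.min()) / (df.max() - df.min())
    response = np.full(params.n_cities, params.intercept)
    for name, coef in params.planted_coefficients.items():
        response = response + coef * scaled[name].to_numpy()
    response = response + rng.normal(0.0, params.noise_sd, params.n_cities)
    clipped = int(((response < 0) | (response > 1)).sum())
    if clipped:
        log.warning("gen_city_collection: clipped %d of %d responses to [0,1]",
                    clipped, params.n_cities)
    df["gini"] = np.clip(response, 0.0, 1.0)
    truth = {"intercept": params.intercept, **params.planted_coefficients}
    return df, truth
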