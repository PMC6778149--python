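"""Synthetic multi-region climate worlds with known niche geometry.

Real multi-range niche studies rest on two inputs that rarely ship with a
paper: gridded climate layers and compiled occurrence coordinates.  This
module builds self-contained stand-ins — several rectangular regions with
spatially autocorrelated, cross-correlated climate fields, and occurrence
records sampled in proportion to a Gaussian suitability surface defined
in climate space — so that every downstream statistic (overlap,
dynamics, divergence, geometric overlap, reciprocal models) can be
checked against a known generating truth.

The generator makes no attempt to mimic real bioclimatic marginal
distributions or land/ocean geometry; its purpose is controlled niche
configurations (identical, nested, shifted, disjoint, and a five-range
layout) whose true overlap can be computed by numerical integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grids import ClimateStack
from .prep import OccurrenceSet

PREDICTORS = ["bio2", "bio5", "bio11", "bio12", "bio15"]

# Deterministic trend of each predictor across a region, expressed in the
# region's local fractional coordinates fx (west->east) and fy
# (south->north): value = base + ax*fx + ay*fy.  Units are the predictor's
# own (degC, mm, %).  Every predictor varies along the SW->NE diagonal so
# that niche positions placed along that diagonal separate in all five
# variables at once.
_TREND = {
    "bio2": (6.0, 4.0, 0.0),
    "bio5": (22.0, 0.0, 10.0),
    "bio11": (-5.0, 5.0, 7.0),
    "bio12": (600.0, 900.0, 0.0),
    "bio15": (30.0, 10.0, 30.0),
}
# Marginal standard deviation of the stochastic field per predictor.
_SILL_SD = {"bio2": 0.3, "bio5": 0.8, "bio11": 1.0, "bio12": 80.0, "bio15": 5.0}
# Effective span of each trend along the SW->NE diagonal (|ax| + |ay|).
_SPAN = {v: abs(a) + abs(b) for v, (_, a, b) in _TREND.items()}


@dataclass
class RegionSpec:
    name: str
    west: float
    south: float
    width: float = 8.0
    height: float = 8.0
    cell_size: float = 0.1

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.width <= 0 or self.height <= 0:
            raise ValueError("region dimensions and cell size must be positive")


@dataclass
class ClimateModel:
    """Trend + Gaussian-random-field parameters shared by all regions."""

    variables: list[str] = field(default_factory=lambda: list(PREDICTORS))
    trend: dict = field(default_factory=lambda: dict(_TREND))
    sill_sd: dict = field(default_factory=lambda: dict(_SILL_SD))
    #: spatial autocorrelation range of the field, in degrees
    corr_range: float = 0.4
    #: cross-variable correlation matrix of the stochastic fields
    cross_corr: np.ndarray | None = None

    def cross(self) -> np.ndarray:
        m = np.eye(len(self.variables)) if self.cross_corr is None \
            else np.asarray(self.cross_corr, dtype=float)
        if m.shape != (len(self.variables),) * 2 or not np.allclose(m, m.T):
            raise ValueError("cross-correlation matrix must be square symmetric")
        ev = np.linalg.eigvalsh(m)
        if ev.min() < -1e-10:
            raise ValueError("cross-correlation matrix must be positive semi-definite")
        return m


@dataclass
class NicheSpec:
    """Gaussian suitability surface in climate space for one range."""

    range_label: str
    region: str
    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.cov.shape != (self.mean.size,) * 2:
            raise ValueError("cov must be square and match mean")


@dataclass
class ScenarioSpec:
    regions: list[RegionSpec]
    climate: ClimateModel
    niches: list[NicheSpec]
    seed: int
    name: str = "custom"

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"unknown region {name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "regions": [vars(r) for r in self.regions],
            "climate": {
                "variables": self.climate.variables,
                "trend": self.climate.trend,
                "sill_sd": self.climate.sill_sd,
                "corr_range": self.climate.corr_range,
                "cross_corr": None if self.climate.cross_corr is None
                else np.asarray(self.climate.cross_corr).tolist(),
            },
            "niches": [
                {"range_label": h.range_label, "region": h.region,
                 "mean": h.mean.tolist(), "cov": h.cov.tolist(), "n": h.n}
                for h in self.niches
            ],
        }


def _trend_layer(model: ClimateModel, var: str, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    base, ax, ay = model.trend[var]
    return base + ax * fx + ay * fy


def make_climate(spec: ScenarioSpec, region_name: str,
                 land_fraction: float = 1.0) -> ClimateStack:
    """Generate the climate raster stack for one region of a scenario.

    Each layer is a deterministic trend plus a stationary Gaussian random
    field produced by convolution filtering of white noise (periodic
    boundary), standardized and mixed across variables through the
    Cholesky factor of the cross-correlation matrix.  ``land_fraction``
    below 1 masks a random subset of cells as NoData.

    The same (spec, region) pair always yields the identical raster.
    """
    region = spec.region(region_name)
    ridx = [r.name for r in spec.regions].index(region_name)
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1000 + ridx])
    model = spec.climate
    ny = int(round(region.height / region.cell_size))
    nx = int(round(region.width / region.cell_size))
    fx, fy = np.meshgrid((np.arange(nx) + 0.5) / nx, (np.arange(ny) + 0.5) / ny)
    fy = fy[::-1]  # row 0 is the northern edge
    nvar = len(model.variables)

    sills = np.array([model.sill_sd[v] for v in model.variables])
    if (sills > 0).any():
        sigma_cells = max(model.corr_range / region.cell_size, 1e-9)
        noise = rng.standard_normal((nvar, ny, nx))
        fields = np.empty_like(noise)
        for k in range(nvar):
            f = ndimage.gaussian_filter(noise[k], sigma_cells, mode="wrap")
            f -= f.mean()
            sd = f.std()
            fields[k] = f / sd if sd > 0 else f
        L = np.linalg.cholesky(model.cross() + 1e-12 * np.eye(nvar))
        fields = np.tensordot(L, fields, axes=(1, 0))
    else:
        fields = np.zeros((nvar, ny, nx))

    data = np.empty((nvar, ny, nx))
    for k, var in enumerate(model.variables):
        data[k] = _trend_layer(model, var, fx, fy) + sills[k] * fields[k]

    if land_fraction < 1.0:
        sea = rng.random((ny, nx)) >= land_fraction
        data[:, sea] = np.nan

    return ClimateStack(
        variables=list(model.variables),
        data=data,
        west=region.west,
        north=region.south + region.height,
        cell_size=region.cell_size,
        region=region_name,
        meta={"scenario": spec.name, "seed": spec.seed},
    )


def true_cell_suitability(stack: ClimateStack, niche_mean, niche_cov) -> np.ndarray:
    """Normalized Gaussian suitability of every raster cell.

    Returns a (n_rows, n_cols) array summing to 1 over valid cells (NaN on
    NoData): the exact occupancy distribution from which
    :func:`sample_occurrences` draws.  This is the generating truth used
    by brute-force overlap oracles.
    """
    mask = stack.land_mask()
    clim = stack.data[:, mask].T
    logp = stats.multivariate_normal(mean=np.asarray(niche_mean, float),
                                     cov=np.asarray(niche_cov, float),
                                     allow_singular=False).logpdf(clim)
    logp = np.atleast_1d(logp)
    w = np.exp(logp - logp.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("niche has zero suitability over the raster")
    out = np.full(stack.shape, np.nan)
    out[mask] = w / total
    return out


def sample_occurrences(stack: ClimateStack, niche_mean, niche_cov, n: int,
                       seed: int, range_label: str = "range") -> OccurrenceSet:
    """Sample occurrence points proportional to Gaussian suitability.

    Cells are drawn with replacement with probability proportional to the
    Gaussian density of their climate vector under ``(niche_mean,
    niche_cov)``; each point is then jittered uniformly within its cell so
    coordinates are unique while the climate vector assigned to the point
    (cell-centre extraction) is unchanged.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = true_cell_suitability(stack, niche_mean, niche_cov)
    mask = stack.land_mask()
    if not mask.any():
        raise ValueError("stack has no valid cells")
    rows, cols = np.nonzero(mask)
    weights = p[rows, cols]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=True, p=weights / weights.sum())
    u = rng.random(n)
    v = rng.random(n)
    lon = stack.west + (cols[idx] + u) * stack.cell_size
    lat = stack.north - (rows[idx] + v) * stack.cell_size
    return OccurrenceSet(range_label=range_label, lon=lon, lat=lat)


def sample_scenario(spec: ScenarioSpec) -> dict[str, OccurrenceSet]:
    """Generate occurrences for every niche of a scenario (seeded from
    the scenario seed and the niche index)."""
    out = {}
    for i, niche in enumerate(spec.niches):
        stack = make_climate(spec, niche.region)
        sub_seed = int(
            np.random.default_rng([int(spec.seed) % (2**31), 2000 + i]).integers(2**31)
        )
        out[niche.range_label] = sample_occurrences(
            stack, niche.mean, niche.cov, niche.n, sub_seed, niche.range_label
        )
    return out


def _niche_at(model: ClimateModel, fx: float, fy: float, sd_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Niche mean at a trend location, diagonal covariance scaled to the
    per-variable trend span."""
    mean = np.array([_trend_layer(model, v, np.array(fx), np.array(fy))
                     for v in model.variables], dtype=float)
    sd = np.array([sd_factor * _SPAN[v] for v in model.variables])
    return mean, np.diag(sd**2)


#: niche width as a fraction of each predictor's trend span
_BASE_SD_FACTOR = 0.08
_PRESET_N = 300

PRESETS = ("identical", "nested", "shifted", "disjoint", "five_range_lilium_like")


def make_scenario(preset: str, seed: int) -> ScenarioSpec:
    """Build a preset scenario with known niche configuration.

    Two-range presets (regions A and B share the climate model but are
    independent realizations):

    - ``identical``: both niches share mean and covariance.
    - ``nested``: B's covariance is 4x A's, same mean.
    - ``shifted``: means separated by 2.5 niche standard deviations in
      every predictor (partial overlap).
    - ``disjoint``: means separated by 7.5 pooled standard deviations in
      every predictor (no practical overlap).

    ``five_range_lilium_like`` lays out five ranges with occurrence counts
    105/315/200/30/70 in a configuration qualitatively matching a
    native range nested inside a broad archaeophyte range, one close and
    two distant neophyte ranges.
    """
    model = ClimateModel()
    if preset in ("identical", "nested", "shifted", "disjoint"):
        regions = [RegionSpec("A", west=0.0, south=0.0),
                   RegionSpec("B", west=20.0, south=0.0)]
        f = _BASE_SD_FACTOR
        if preset == "identical":
            locs = [(0.5, 0.5, f), (0.5, 0.5, f)]
        elif preset == "nested":
            locs = [(0.5, 0.5, f), (0.5, 0.5, 2 * f)]
        elif preset == "shifted":
            locs = [(0.4, 0.4, f), (0.6, 0.6, f)]
        else:  # disjoint: 0.6 span separation = 7.5 pooled sd at f = 0.08
            locs = [(0.2, 0.2, f), (0.8, 0.8, f)]
        niches = []
        for (fx, fy, sdf), (label, region) in zip(locs, [("A", "A"), ("B", "B")]):
            mean, cov = _niche_at(model, fx, fy, sdf)
            niches.append(NicheSpec(label, region, mean, cov, _PRESET_N))
        return ScenarioSpec(regions, model, niches, seed, name=preset)

    if preset == "five_range_lilium_like":
        layout = [
            # label, n, (fx, fy), sd factor
            ("native", 105, (0.50, 0.50), 0.08),
            ("ASIA", 315, (0.50, 0.50), 0.16),
            ("USA-CA", 200, (0.56, 0.46), 0.10),
            ("AUS-NZ", 30, (0.36, 0.62), 0.10),
            ("EUR", 70, (0.76, 0.76), 0.07),
        ]
        regions = [RegionSpec(lab, west=20.0 * i, south=0.0)
                   for i, (lab, *_rest) in enumerate(layout)]
        niches = []
        for lab, n, (fx, fy), sdf in layout:
            mean, cov = _niche_at(model, fx, fy, sdf)
            niches.append(NicheSpec(lab, lab, mean, cov, n))
        return ScenarioSpec(regions, model, niches, seed, name=preset)

    raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")


__all__ = [
    "PREDICTORS", "PRESETS", "RegionSpec", "ClimateModel", "NicheSpec",
    "ScenarioSpec", "make_climate", "make_scenario", "sample_occurrences",
    "sample_scenario", "true_cell_suitability",
]
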