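"""Synthetic landscapes, density surfaces and camera-trap detection streams.

Everything downstream of field work — the random encounter model (REM),
suitability thresholding, succession classification and the association
statistics — is testable end-to-end on data produced here.  The generators
emulate the statistical structure the analysis assumes:

* a patchy Mediterranean land-cover mosaic (CLC level-III codes) built by
  multi-seed region growing;
* ungulate density decaying exponentially with distance from a release
  point, confined to suitable habitat;
* per-camera detection counts that are Poisson with the REM encounter rate
  ``t * D * v * r * (2 + theta) / pi``, so the REM estimator is the exact
  inverse of the forward model;
* a second land-cover epoch in which grassland/shrub cells advance one
  succession rank with probability decreasing in local grazer density, and
  revert with probability increasing in it.

All generators are deterministic given a seed; one root seed expands into
independent per-stage substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .raster import GridMismatchError, Raster
from .rem import Deployment, DetectionRecord

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "TrueDensityField",
    "BurstConfig",
    "SuccessionChangeParams",
    "CLC_CODES",
    "SUCCESSION_RANK",
    "generate_landscape",
    "simulate_density_field",
    "simulate_detections",
    "simulate_landcover_change",
]

# CLC level-III code table used throughout: 311/312/313 forests, 321
# grassland, 322/323 shrub, 324 transitional woodland-shrub, 211 arable
# (agricultural, class 2), 333 sparsely vegetated (rank-0 class 3).
CLC_CODES: dict[int, str] = {
    211: "arable",
    311: "broadleaf forest",
    312: "conifer forest",
    313: "mixed forest",
    321: "grassland",
    322: "moors and heathland",
    323: "sclerophyllous shrub",
    324: "transitional woodland-shrub",
    333: "sparsely vegetated",
}

# Succession rank within class 3: 0 bare/other, 1 grassland, 2 shrub or
# transitional, 3 forest.  Canonical representative code per rank, used when
# a cell moves one rank in the change simulator.
SUCCESSION_RANK: dict[int, int] = {
    311: 3, 312: 3, 313: 3,
    321: 1,
    322: 2, 323: 2, 324: 2,
    331: 0, 332: 0, 333: 0, 334: 0, 335: 0,
}
_CANONICAL_CODE = {0: 333, 1: 321, 2: 322, 3: 311}


class InvalidConfigError(ValueError):
    pass


class NoSupportError(ValueError):
    """An operation requires at least one suitable cell and found none."""


class PlacementError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    """Settings for :func:`generate_landscape`.

    ``class_weights`` is the mixture over land-cover codes that patch seeds
    are drawn from; the realised areal fractions approximate these weights.
    Defaults sketch an Apennine mosaic: mostly forest and shrub with
    interspersed grassland and agricultural patches.
    """

    extent_m: tuple[float, float] = (20_000.0, 20_000.0)
    resolution_m: float = 100.0
    seed: int = 0
    n_patches: int = 120
    class_weights: dict[int, float] = field(
        default_factory=lambda: {
            311: 0.22, 312: 0.08, 313: 0.10,
            321: 0.20, 322: 0.10, 323: 0.08, 324: 0.07,
            211: 0.15,
        }
    )
    elevation_range_m: tuple[float, float] = (100.0, 1900.0)
    elevation_smoothness: float = 8.0  # gaussian sigma in cells
    release_point: tuple[float, float] | None = None  # default: centre
    crs: str = "local-metric"

    def validate(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise InvalidConfigError("extent must be positive")
        if self.resolution_m <= 0:
            raise InvalidConfigError("resolution must be positive")
        for w, r in ((self.extent_m[0], "width"), (self.extent_m[1], "height")):
            if abs(w / self.resolution_m - round(w / self.resolution_m)) > 1e-9:
                raise InvalidConfigError(f"extent {r} not divisible by resolution")
        if self.n_patches < 1:
            raise InvalidConfigError("need at least one patch seed")
        if not self.class_weights or any(v < 0 for v in self.class_weights.values()):
            raise InvalidConfigError("class weights must be non-negative and non-empty")
        for code in self.class_weights:
            if code not in CLC_CODES:
                raise InvalidConfigError(f"unknown land-cover code {code}")


@dataclass
class LandscapeBundle:
    """Aligned rasters plus the release point for one synthetic study area."""

    landcover_epoch1: Raster  # categorical CLC level-III codes
    elevation: Raster         # m a.s.l.
    suitability: dict[str, Raster]  # per-species, values in [0, 1]
    release_point: tuple[float, float]
    resolution: float

    def grid(self) -> Raster:
        return self.landcover_epoch1


@dataclass
class TrueDensityField:
    """Ground-truth density surface (ind/km^2) integrating to a known N."""

    species: str
    surface: Raster
    total_abundance: float


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a land-cover mosaic, elevation and suitability on one grid.

    The mosaic allocates every cell to its nearest patch seed (uniform-rate
    region growing); seeds carry codes drawn from ``class_weights``.
    Elevation is a smoothed Gaussian random field rescaled to
    ``elevation_range_m``.  Suitability is a logistic preference for
    mid-to-high elevations plus smooth spatial noise, squashed into [0, 1];
    two species ("roe_deer", "red_deer") with slightly different optima are
    produced, plus a "livestock" layer favouring lower elevations.
    """
    config.validate()
    rng_patch, rng_elev, rng_suit = _substreams(config.seed, 3)

    ncols = int(round(config.extent_m[0] / config.resolution_m))
    nrows = int(round(config.extent_m[1] / config.resolution_m))
    template = Raster(
        data=np.zeros((nrows, ncols)),
        xmin=0.0,
        ymax=config.extent_m[1],
        resolution=config.resolution_m,
        crs=config.crs,
    )

    # mosaic: nearest patch seed wins (Voronoi allocation)
    codes = np.array(sorted(config.class_weights))
    weights = np.array([config.class_weights[c] for c in codes], dtype=float)
    weights = weights / weights.sum()
    seed_rows = rng_patch.uniform(0, nrows, config.n_patches)
    seed_cols = rng_patch.uniform(0, ncols, config.n_patches)
    seed_codes = rng_patch.choice(codes, size=config.n_patches, p=weights)
    ii, jj = np.mgrid[0:nrows, 0:ncols]
    d2 = (ii[..., None] - seed_rows) ** 2 + (jj[..., None] - seed_cols) ** 2
    landcover = seed_codes[np.argmin(d2, axis=-1)].astype(int)

    # elevation: smoothed white noise, rescaled
    noise = rng_elev.standard_normal((nrows, ncols))
    smooth = ndimage.gaussian_filter(noise, sigma=config.elevation_smoothness)
    lo, hi = config.elevation_range_m
    smin, smax = smooth.min(), smooth.max()
    if smax > smin:
        elevation = lo + (smooth - smin) / (smax - smin) * (hi - lo)
    else:
        elevation = np.full((nrows, ncols), 0.5 * (lo + hi))

    def _suit(optimum: float, width: float, rng: np.random.Generator) -> np.ndarray:
        pref = np.exp(-0.5 * ((elevation - optimum) / width) ** 2)
        wig = ndimage.gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=6.0)
        s = expit(4.0 * (pref - 0.35) + 1.5 * wig)
        return np.clip(s, 0.0, 1.0)

    sub = _substreams(int(rng_suit.integers(2**31)), 3)
    suitability = {
        "roe_deer": template.like(_suit(1100.0, 450.0, sub[0])),
        "red_deer": template.like(_suit(1300.0, 400.0, sub[1])),
        "livestock": template.like(_suit(700.0, 500.0, sub[2])),
    }

    release = config.release_point
    if release is None:
        release = (config.extent_m[0] / 2.0, config.extent_m[1] / 2.0)

    return LandscapeBundle(
        landcover_epoch1=template.like(landcover),
        elevation=template.like(elevation),
        suitability=suitability,
        release_point=release,
        resolution=config.resolution_m,
    )


def distance_from_release_km(grid: Raster, release_point: tuple[float, float]) -> np.ndarray:
    """Euclidean distance (km) from every cell centre to the release point."""
    X, Y = grid.cell_centers()
    return np.hypot(X - release_point[0], Y - release_point[1]) / 1000.0


def simulate_density_field(
    bundle: LandscapeBundle,
    species: str,
    total_abundance: float,
    decay_per_km: float,
    mask: np.ndarray | None = None,
    suitability_threshold: float = 0.5,
) -> TrueDensityField:
    """Exponential distance-decay density surface integrating to N.

    The surface is proportional to ``exp(-decay * distance_to_release_km)``
    on suitable cells (suitability >= threshold, or an explicit boolean
    mask) and zero elsewhere, rescaled so that the spatial integral equals
    ``total_abundance`` individuals.
    """
    if total_abundance < 0:
        raise InvalidConfigError("total abundance must be >= 0")
    if decay_per_km < 0:
        raise InvalidConfigError("decay rate must be >= 0")
    grid = bundle.grid()
    if mask is None:
        if species not in bundle.suitability:
            raise KeyError(f"no suitability layer for species {species!r}")
        mask = bundle.suitability[species].data >= suitability_threshold
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GridMismatchError("mask shape does not match landscape grid")
    if not mask.any():
        raise NoSupportError("suitable mask is empty; density field has no support")

    dist_km = distance_from_release_km(grid, bundle.release_point)
    surface = np.where(mask, np.exp(-decay_per_km * dist_km), 0.0)
    integral = surface.sum() * grid.cell_area_km2
    if total_abundance == 0:
        surface = np.zeros_like(surface)
    else:
        surface = surface * (total_abundance / integral)
    return TrueDensityField(species=species, surface=grid.like(surface), total_abundance=float(total_abundance))


@dataclass
class BurstConfig:
    """Inject sub-independence-window duplicate records.

    Each primary event spawns ``extra_records`` follow-ups ``gap_minutes``
    apart with probability ``per_event_prob``; with a gap below the 10-min
    rule these duplicates exist to exercise the independence filter.
    """

    per_event_prob: float = 0.3
    gap_minutes: float = 5.0
    extra_records: int = 1


def simulate_detections(
    field: TrueDensityField,
    deployments: list[Deployment],
    v_km_per_day: float,
    seed: int,
    min_gap_minutes: float = 10.0,
    bursts: BurstConfig | None = None,
) -> list[DetectionRecord]:
    """Poisson REM forward model.

    For each camera the number of independent events over its deployment is
    Poisson with mean ``t * D_local * v * r_km * (2 + theta) / pi`` — the
    exact inverse of the REM estimator.  Event times are uniform over the
    deployment window, then pushed forward so consecutive events on one
    camera are more than ``min_gap_minutes`` apart (events pushed past the
    window end are dropped; negligible at realistic rates).  Optional bursts
    add closely spaced duplicates for testing the independence filter.
    """
    if v_km_per_day <= 0:
        raise InvalidConfigError("movement speed must be positive")
    grid = field.surface
    rngs = _substreams(seed, max(len(deployments), 1))
    records: list[DetectionRecord] = []
    for dep, rng in zip(deployments, rngs):
        x, y = dep.location
        if not grid.contains_point(x, y):
            raise PlacementError(f"deployment {dep.camera_id} at ({x}, {y}) outside extent")
        i, j = grid.index_of(x, y)
        d_local = float(grid.data[i, j])
        t_days = dep.trap_days
        r_km = dep.spec.r_m / 1000.0
        rate = t_days * d_local * v_km_per_day * r_km * (2.0 + dep.spec.theta_rad) / math.pi
        n = int(rng.poisson(rate))
        if n == 0:
            continue
        window_s = t_days * 86400.0
        offsets = np.sort(rng.uniform(0.0, window_s, size=n))
        gap_s = min_gap_minutes * 60.0
        kept_offsets: list[float] = []
        last = -np.inf
        for off in offsets:
            t = max(off, last + gap_s + 1.0)
            if t > window_s:
                continue  # pushed past deployment end
            kept_offsets.append(t)
            last = t
        for off in kept_offsets:
            ts = dep.start + timedelta(seconds=float(off))
            records.append(DetectionRecord(dep.camera_id, field.species, ts, 1))
            if bursts is not None and rng.uniform() < bursts.per_event_prob:
                for k in range(1, bursts.extra_records + 1):
                    bt = ts + timedelta(minutes=k * bursts.gap_minutes)
                    if bt <= dep.end:
                        records.append(DetectionRecord(dep.camera_id, field.species, bt, 1))
    records.sort(key=lambda rec: (rec.camera_id, rec.species, rec.timestamp))
    return records


@dataclass
class SuccessionChangeParams:
    """Logistic coefficients linking grazer density to succession moves.

    P(advance one rank) = expit(advance_intercept - advance_slope * density)
    P(revert one rank)  = expit(revert_intercept + revert_slope * density)

    Slopes are >= 0 so grazing suppresses forest encroachment (advance) and
    promotes opening (reversion).  Use ``-inf`` intercepts for exact zeros.
    """

    advance_intercept: float = -1.0
    advance_slope: float = 1.0
    revert_intercept: float = -4.0
    revert_slope: float = 0.5

    def validate(self) -> None:
        if self.advance_slope < 0 or self.revert_slope < 0:
            raise InvalidConfigError("slopes must be >= 0")


def simulate_landcover_change(
    bundle: LandscapeBundle,
    grazer_density: Raster,
    params: SuccessionChangeParams,
    seed: int,
) -> Raster:
    """Second-epoch land cover with grazing-dependent succession.

    Each class-3 cell advances one succession rank (toward forest) or
    reverts one rank with the logistic probabilities in ``params``
    evaluated at its local grazer density; non-class-3 cells are copied
    unchanged.  A cell can do at most one of the two moves (advance is
    evaluated first).
    """
    params.validate()
    grid = bundle.grid()
    grid.require_same_grid(grazer_density, "grazer density")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    codes = bundle.landcover_epoch1.data.astype(int)
    dens = np.asarray(grazer_density.data, dtype=float)
    p_adv = expit(params.advance_intercept - params.advance_slope * dens)
    p_rev = expit(params.revert_intercept + params.revert_slope * dens)

    out = codes.copy()
    class3 = (codes // 100) == 3
    rank = np.full(codes.shape, -1)
    for code, rk in SUCCESSION_RANK.items():
        rank[codes == code] = rk

    u = rng.uniform(size=codes.shape)
    w = rng.uniform(size=codes.shape)
    can_advance = class3 & (rank >= 0) & (rank < 3)
    can_revert = class3 & (rank > 0)
    advance = can_advance & (u < p_adv)
    revert = can_revert & ~advance & (w < p_rev)
    for rk in range(0, 3):
        out[advance & (rank == rk)] = _CANONICAL_CODE[rk + 1]
    for rk in range(1, 4):
        out[revert & (rank == rk)] = _CANONICAL_CODE[rk - 1]
    return grid.like(out)
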