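"""Density interpolation, merging and association statistics.

Per-cell REM estimates are interpolated to continuous surfaces with
inverse-distance weighting (IDW), clipped to suitable habitat, and merged
(wild deer + livestock) into a cumulative grazer density.  The module then
carries the association analyses: a GLM of density against distance from
the release point (gamma or inverse-Gaussian family, canonical link),
Welch's t-test comparing grazing density between succession classes, a
2x2 chi-square of succession occurrence inside/outside suitable habitat,
per-class density summaries, and the elevation comparison restricted to
patches deer do not inhabit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .landcover_change import IS_VALUE, NONE_VALUE, SS_VALUE
from .raster import GridMismatchError, Raster

__all__ = [
    "DensitySurface",
    "GlmFit",
    "TwoSampleResult",
    "idw_interpolate",
    "merge_densities",
    "fit_density_distance_glm",
    "welch_t",
    "chi_square_2x2",
    "class_density_summary",
    "elevation_by_class",
]


class NoDataError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


@dataclass
class DensitySurface:
    """A clipped density raster (ind/km^2) for one species or group."""

    label: str
    raster: Raster  # NaN outside the mask
    mask: np.ndarray  # boolean, True where the surface is defined

    def values(self) -> np.ndarray:
        return np.asarray(self.raster.data, dtype=float)[self.mask]


@dataclass
class GlmFit:
    """Distance-decay GLM summary (density ~ distance from release)."""

    family: str
    link: str
    intercept: float
    slope: float  # per km of distance
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    pseudo_r2: float
    n: int
    aic: float
    bic: float


@dataclass
class TwoSampleResult:
    statistic: float
    df: float
    p_value: float
    means: tuple[float, float]
    ses: tuple[float, float]
    ns: tuple[int, int]


def idw_interpolate(
    sample_points: np.ndarray,
    sample_values: np.ndarray,
    grid: Raster,
    power: float = 2.0,
    mask: np.ndarray | None = None,
    label: str = "density",
) -> DensitySurface:
    """Inverse-distance-weighted interpolation onto a grid.

    Cell value = sum(w_i z_i) / sum(w_i) with w_i = d_i^-power over ALL
    samples (no neighbour cutoff).  A cell whose centre coincides with a
    sample takes that sample's value exactly.  The result is clipped to
    ``mask`` (NaN outside); with no mask the full grid is interpolated.
    """
    pts = np.atleast_2d(np.asarray(sample_points, dtype=float))
    vals = np.asarray(sample_values, dtype=float)
    if pts.shape[0] == 0:
        raise NoDataError("no sample points for interpolation")
    if power <= 0:
        raise ValueError("IDW power must be positive")
    if pts.shape[0] != vals.shape[0]:
        raise ValueError("sample points and values length mismatch")

    X, Y = grid.cell_centers()
    dx = X.ravel()[:, None] - pts[None, :, 0]
    dy = Y.ravel()[:, None] - pts[None, :, 1]
    d = np.hypot(dx, dy)
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[exact] = np.inf
    surf = np.empty(d.shape[0])
    any_exact = exact.any(axis=1)
    if any_exact.any():
        first = np.argmax(exact[any_exact], axis=1)
        surf[any_exact] = vals[first]
    finite = ~any_exact
    surf[finite] = (w[finite] * vals).sum(axis=1) / w[finite].sum(axis=1)
    surf = surf.reshape(grid.shape)

    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GridMismatchError("mask shape does not match grid")
    surf = np.where(mask, surf, np.nan)
    return DensitySurface(label=label, raster=grid.like(surf, nodata=np.nan), mask=mask)


def merge_densities(surfaces: list[DensitySurface], label: str = "cumulative") -> DensitySurface:
    """Cell-wise sum of density surfaces (cumulative grazer density).

    Nodata counts as zero wherever at least one layer is valid; cells valid
    in no layer stay nodata.  Commutative and associative.
    """
    if not surfaces:
        raise NoDataError("nothing to merge")
    grid = surfaces[0].raster
    for s in surfaces[1:]:
        grid.require_same_grid(s.raster, f"surface {s.label!r}")
    any_valid = np.zeros(grid.shape, dtype=bool)
    total = np.zeros(grid.shape, dtype=float)
    for s in surfaces:
        any_valid |= s.mask
        total += np.where(s.mask, np.nan_to_num(s.raster.data, nan=0.0), 0.0)
    total = np.where(any_valid, total, np.nan)
    return DensitySurface(label=label, raster=grid.like(total, nodata=np.nan), mask=any_valid)


_FAMILIES = {
    "gamma": lambda: sm.families.Gamma(),               # canonical inverse link
    "inverse-gaussian": lambda: sm.families.InverseGaussian(),  # 1/mu^2 link
}


def fit_density_distance_glm(
    density: DensitySurface,
    distance_km: Raster,
    family: str = "gamma",
    zero_shift: float | None = None,
) -> GlmFit:
    """GLM of cell density on distance from the release point.

    Canonical links are used (inverse for gamma, 1/mu^2 for inverse
    Gaussian), under which a POSITIVE slope corresponds to density
    decreasing with distance.  Zero densities, outside the support of both
    families, are shifted by ``zero_shift`` (default: half the smallest
    positive value; logged via a warning).  Pseudo-R^2 is deviance-based:
    1 - residual deviance / null deviance.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
    density.raster.require_same_grid(distance_km, "distance raster")
    yv = density.values()
    xv = np.asarray(distance_km.data, dtype=float)[density.mask]
    keep = np.isfinite(yv) & np.isfinite(xv)
    yv, xv = yv[keep], xv[keep]
    if yv.size < 10:
        raise InsufficientDataError("need at least 10 valid cells for the GLM")

    if (yv <= 0).any():
        if zero_shift is None:
            positive = yv[yv > 0]
            if positive.size == 0:
                raise InsufficientDataError("response is identically zero")
            zero_shift = float(positive.min() / 2.0)
        warnings.warn(
            f"{int((yv <= 0).sum())} non-positive densities shifted by {zero_shift:g} "
            "to fit the strictly positive GLM family"
        )
        yv = yv + zero_shift

    if np.ptp(yv) == 0.0:
        # constant response: flat fit, no deviance explained
        return GlmFit(
            family=family, link=type(_FAMILIES[family]().link).__name__,
            intercept=float(_FAMILIES[family]().link(yv[0])), slope=0.0,
            intercept_se=0.0, slope_se=0.0, intercept_p=0.0, slope_p=1.0,
            pseudo_r2=0.0, n=int(yv.size), aic=float("nan"), bic=float("nan"),
        )

    exog = sm.add_constant(xv)
    fam = _FAMILIES[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels domain warnings on edge fits
        res = sm.GLM(yv, exog, family=fam).fit()
    if not res.converged:
        raise RuntimeError(f"GLM ({family}) failed to converge: {res.mle_retvals}")
    pseudo_r2 = 1.0 - res.deviance / res.null_deviance
    return GlmFit(
        family=family,
        link=type(fam.link).__name__,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        intercept_p=float(res.pvalues[0]),
        slope_p=float(res.pvalues[1]),
        pseudo_r2=float(pseudo_r2),
        n=int(yv.size),
        aic=float(res.aic),
        bic=float(res.bic_llf),
    )


def _summ(x: np.ndarray) -> tuple[float, float, int]:
    n = x.size
    se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(x)), se, n


def welch_t(a, b) -> TwoSampleResult:
    """Welch's unequal-variance t-test (two-sided, Satterthwaite df)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    ma, sea, na = _summ(a)
    mb, seb, nb = _summ(b)
    if sea == 0.0 and seb == 0.0:
        # degenerate zero-variance samples: no evidence either way
        t = 0.0 if ma == mb else math.inf * math.copysign(1.0, ma - mb)
        return TwoSampleResult(
            statistic=t, df=float(na + nb - 2),
            p_value=1.0 if t == 0.0 else 0.0,
            means=(ma, mb), ses=(sea, seb), ns=(na, nb),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical data
        res = stats.ttest_ind(a, b, equal_var=False)
    return TwoSampleResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        means=(ma, mb),
        ses=(sea, seb),
        ns=(na, nb),
    )


def chi_square_2x2(table) -> TwoSampleResult:
    """Pearson chi-square on a 2x2 contingency table, df=1, no correction.

    Algebraically equal to N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("a marginal total is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    (a, b), (c, d) = t
    return TwoSampleResult(
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        means=(a / (a + b), c / (c + d)),  # row proportions in column 1
        ses=(0.0, 0.0),
        ns=(int(a + b), int(c + d)),
    )


def class_density_summary(
    density: DensitySurface, change: Raster
) -> dict[str, dict[str, float]]:
    """Mean, SE (SD/sqrt n) and cell count of density per succession class.

    Only cells inside the density surface's mask contribute.  Classes with
    zero cells are reported as absent (left out of the result).
    """
    density.raster.require_same_grid(change, "change raster")
    vals = np.asarray(density.raster.data, dtype=float)
    cls = np.asarray(change.data, dtype=int)
    out: dict[str, dict[str, float]] = {}
    for name, value in (("SS", SS_VALUE), ("IS", IS_VALUE), ("none", NONE_VALUE)):
        sel = density.mask & (cls == value) & np.isfinite(vals)
        if not sel.any():
            continue
        mean, se, n = _summ(vals[sel])
        out[name] = {"mean": mean, "se": se, "n": n}
    return out


def elevation_by_class(
    elevation: Raster, change: Raster, exclude_mask: np.ndarray
) -> TwoSampleResult:
    """Two-sample t of elevation, SS vs IS cells, outside an excluded area.

    ``exclude_mask`` marks cells to leave out — typically the deer-suitable
    habitat, so the comparison runs over patches deer do not inhabit and a
    null result argues against elevation driving the succession pattern.
    """
    elevation.require_same_grid(change, "change raster")
    exclude = np.asarray(exclude_mask, dtype=bool)
    if exclude.shape != elevation.shape:
        raise GridMismatchError("exclude mask shape does not match grid")
    elev = np.asarray(elevation.data, dtype=float)
    cls = np.asarray(change.data, dtype=int)
    ss = elev[~exclude & (cls == SS_VALUE) & np.isfinite(elev)]
    is_ = elev[~exclude & (cls == IS_VALUE) & np.isfinite(elev)]
    if ss.size < 2 or is_.size < 2:
        raise InsufficientDataError(
            f"need >= 2 cells per class outside the excluded area "
            f"(SS: {ss.size}, IS: {is_.size})"
        )
    return welch_t(ss, is_)
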