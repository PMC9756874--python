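"""Habitat-suitability predictor preparation and thresholding.

The species distribution model itself is an external input: this module
prepares predictors (Euclidean-distance rasters to landscape features, a
Pearson collinearity screen) and converts any continuous suitability
surface in [0, 1] into the discrete masks the downstream analysis uses,
via two standard presence-based thresholds:

* the 10th-percentile training-presence threshold (the score below which
  the lowest decile of presence records fall), and
* the maximum sensitivity-plus-specificity (maxSSS) threshold against a
  background-score sample.

Cells at or above maxSSS are "high" suitability, cells between the two
thresholds "medium", the rest unsuitable; medium + high is the total
suitable area used as the clipping mask downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.strtree import STRtree

from .raster import Raster

__all__ = [
    "SuitabilityThresholds",
    "SuitabilityLevels",
    "distance_raster",
    "collinearity_screen",
    "percentile_threshold",
    "max_sss_threshold",
    "classify_levels",
]

UNSUITABLE, MEDIUM, HIGH = 0, 1, 2


class NoDataError(ValueError):
    pass


@dataclass(frozen=True)
class SuitabilityThresholds:
    """The two presence-based cut points on a [0, 1] suitability score."""

    p10: float
    maxsss: float

    def __post_init__(self) -> None:
        for name, v in (("p10", self.p10), ("maxsss", self.maxsss)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} threshold must lie in [0, 1]")


@dataclass
class SuitabilityLevels:
    """Three-level classification with an area report in km^2."""

    raster: Raster  # values UNSUITABLE/MEDIUM/HIGH, nodata preserved
    area_km2: dict[str, float]  # keys: unsuitable, medium, high, total_suitable


def distance_raster(features, grid: Raster) -> Raster:
    """Euclidean distance (m) from each cell centre to the nearest feature.

    ``features`` is any iterable of shapely geometries (points, lines or
    polygons).  Cells whose centre lies on/inside a feature get 0.
    """
    feats = list(features)
    if not feats:
        raise NoDataError("empty feature set")
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    tree = STRtree(feats)
    _, dist = tree.query_nearest(pts, return_distance=True, all_matches=False)
    return grid.like(dist.reshape(grid.shape))


def collinearity_screen(
    predictors: dict[str, Raster], threshold: float = 0.7
) -> tuple[list[str], list[str], "np.ndarray"]:
    """Greedy Pearson collinearity screen over a predictor stack.

    Pairwise Pearson r is computed over cells valid in every layer.  While
    any retained pair exceeds ``|r| >= threshold``, the member of the worst
    offending pair with the larger mean absolute correlation (against all
    retained variables) is dropped; name order breaks exact ties, so the
    procedure is deterministic.  Constant predictors have undefined
    correlation and are dropped up front with a warning.

    Returns (retained names, dropped names, correlation matrix over the
    original stack in input order; rows of dropped-constant variables are
    NaN).
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    names = list(predictors)
    grids = [predictors[n] for n in names]
    for g in grids[1:]:
        grids[0].require_same_grid(g, "predictor")

    valid = np.ones(grids[0].shape, dtype=bool)
    for g in grids:
        valid &= g.valid_mask()
    stack = np.array([np.asarray(g.data, dtype=float)[valid] for g in grids])

    dropped: list[str] = []
    constant = [n for n, col in zip(names, stack) if np.std(col) == 0]
    for n in constant:
        warnings.warn(f"predictor {n!r} is constant: correlation undefined, dropped")
        dropped.append(n)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(stack)
    corr = np.atleast_2d(corr)

    retained = [n for n in names if n not in dropped]
    while True:
        idx = [names.index(n) for n in retained]
        sub = np.abs(corr[np.ix_(idx, idx)])
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or np.nanmax(sub) < threshold:
            break
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        mean_i = np.nanmean(np.delete(sub[i], i))
        mean_j = np.nanmean(np.delete(sub[j], j))
        if mean_i > mean_j:
            loser = retained[i]
        elif mean_j > mean_i:
            loser = retained[j]
        else:  # exact tie: drop the later name in input order
            loser = max(retained[i], retained[j], key=names.index)
        retained.remove(loser)
        dropped.append(loser)
    return retained, dropped, corr


def percentile_threshold(presence_scores, pct: float = 10.0) -> float:
    """Percentile of the training-presence score distribution.

    Linear interpolation between order statistics; pct=10 gives the
    10th-percentile training-presence threshold.
    """
    scores = np.asarray(list(presence_scores), dtype=float)
    if scores.size == 0:
        raise NoDataError("no presence scores")
    return float(np.percentile(scores, pct, method="linear"))


def max_sss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity (maxSSS).

    Candidates are the sorted unique scores of both samples; sensitivity is
    the fraction of presences with score >= threshold and specificity the
    fraction of background with score < threshold.  Ties resolve to the
    lowest threshold.
    """
    pres = np.asarray(list(presence_scores), dtype=float)
    back = np.asarray(list(background_scores), dtype=float)
    if pres.size == 0 or back.size == 0:
        raise NoDataError("presence and background scores must be non-empty")
    candidates = np.unique(np.concatenate([pres, back]))
    best_thr, best_val = None, -np.inf
    for thr in candidates:  # ascending, so strict > keeps the lowest tie
        sens = np.mean(pres >= thr)
        spec = np.mean(back < thr)
        if sens + spec > best_val + 1e-12:
            best_val = sens + spec
            best_thr = thr
    return float(best_thr)


def classify_levels(
    suitability: Raster, thresholds: SuitabilityThresholds
) -> SuitabilityLevels:
    """Partition a continuous suitability raster into three levels.

    high: score >= maxsss; medium: p10 <= score < maxsss; unsuitable
    otherwise.  Nodata cells stay out of every class.  The area report (in
    km^2) includes the total suitable area (medium + high), which serves as
    the downstream clipping mask.
    """
    if thresholds.maxsss < thresholds.p10:
        warnings.warn(
            "maxSSS threshold below the 10th-percentile threshold; "
            "medium level will be empty"
        )
    valid = suitability.valid_mask()
    score = np.asarray(suitability.data, dtype=float)
    levels = np.full(suitability.shape, UNSUITABLE, dtype=float)
    levels[valid & (score >= thresholds.p10)] = MEDIUM
    levels[valid & (score >= thresholds.maxsss)] = HIGH
    levels[~valid] = np.nan

    a = suitability.cell_area_km2
    areas = {
        "unsuitable": float(np.sum(valid & (levels == UNSUITABLE)) * a),
        "medium": float(np.sum(levels == MEDIUM) * a),
        "high": float(np.sum(levels == HIGH) * a),
    }
    areas["total_suitable"] = areas["medium"] + areas["high"]
    out = suitability.like(levels, nodata=np.nan)
    return SuitabilityLevels(raster=out, area_km2=areas)
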