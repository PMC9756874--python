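"""Land-cover change detection and succession classification.

Two CLC level-III epochs are overlaid, sliver polygons below 0.25 ha are
dropped as misalignment artifacts, and each change is classified along the
vegetation succession axis within class 3 (forest and semi-natural areas):

* Spontaneous Succession (SS): a class-3 patch moves to a MORE advanced
  stage (grassland -> shrub, shrub -> forest) — forest encroachment;
* Inverse Succession (IS): a class-3 patch moves to a LESS advanced stage
  (forest -> shrub, shrub -> grassland) — landscape opening.

Succession ranks: 0 bare/open (331-335), 1 grassland (321), 2 shrub or
transitional (322-324), 3 forest (311-313).  Transitions within one rank
(e.g. 322 -> 323) and any transition touching class 1/2/4/5 are "none".
Classified changes are rasterized at the analysis resolution (100 m) by
the cell-centre rule for comparison with density surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .raster import GridMismatchError, Raster
from .synthetic_data import SUCCESSION_RANK

__all__ = [
    "ChangeClass",
    "ChangePolygon",
    "classify_succession",
    "overlay_epochs",
    "clean_small",
    "rasterize_changes",
    "NONE_VALUE",
    "SS_VALUE",
    "IS_VALUE",
]

NONE_VALUE, SS_VALUE, IS_VALUE = 0, 1, 2


class ChangeClass(str, Enum):
    SS = "SS"
    IS = "IS"
    NONE = "none"


class ClassificationError(ValueError):
    pass


@dataclass
class ChangePolygon:
    """One contiguous piece of land whose cover code changed between epochs."""

    geometry: shapely.Geometry
    code_from: int
    code_to: int
    change_class: ChangeClass = ChangeClass.NONE

    @property
    def area_m2(self) -> float:
        return self.geometry.area

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0


def _rank(code: int) -> int | None:
    return SUCCESSION_RANK.get(code)


def classify_succession(code_from: int, code_to: int) -> ChangeClass:
    """Classify one transition as SS, IS or none.

    Both codes must be CLC class 3 for a succession label; the direction of
    the rank change decides between SS (advance) and IS (reversion).
    Unknown codes raise a classification error naming the code.
    """
    for code in (code_from, code_to):
        if not isinstance(code, (int, np.integer)) or not (100 <= code <= 599):
            raise ClassificationError(f"unknown land-cover code: {code}")
    if code_from // 100 != 3 or code_to // 100 != 3:
        return ChangeClass.NONE
    rf, rt = _rank(code_from), _rank(code_to)
    if rf is None:
        raise ClassificationError(f"class-3 code without succession rank: {code_from}")
    if rt is None:
        raise ClassificationError(f"class-3 code without succession rank: {code_to}")
    if rt > rf:
        return ChangeClass.SS
    if rt < rf:
        return ChangeClass.IS
    return ChangeClass.NONE


def _overlay_vectors(epoch1, epoch2) -> list[ChangePolygon]:
    """Pairwise intersection of two (geometry, code) polygon layers."""
    tree = STRtree([g for g, _ in epoch2])
    out: list[ChangePolygon] = []
    for geom1, code1 in epoch1:
        for idx in tree.query(geom1):
            geom2, code2 = epoch2[idx]
            piece = geom1.intersection(geom2)
            if piece.is_empty or piece.area == 0:
                continue
            out.append(ChangePolygon(piece, int(code1), int(code2)))
    return out


def _overlay_rasters(epoch1: Raster, epoch2: Raster) -> list[ChangePolygon]:
    """Cell-wise overlay; connected changed regions become polygons."""
    epoch1.require_same_grid(epoch2, "epoch-2 raster")
    c1 = np.asarray(epoch1.data, dtype=int)
    c2 = np.asarray(epoch2.data, dtype=int)
    res = epoch1.resolution
    out: list[ChangePolygon] = []
    pairs = {(int(a), int(b)) for a, b in zip(c1.ravel(), c2.ravel())}
    for code_from, code_to in sorted(pairs):
        cells = (c1 == code_from) & (c2 == code_to)
        labels, n = ndimage.label(cells)
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(labels == comp)
            boxes = [
                box(
                    epoch1.xmin + j * res,
                    epoch1.ymax - (i + 1) * res,
                    epoch1.xmin + (j + 1) * res,
                    epoch1.ymax - i * res,
                )
                for i, j in zip(rows, cols)
            ]
            out.append(ChangePolygon(unary_union(boxes), code_from, code_to))
    return out


def overlay_epochs(epoch1, epoch2) -> list[ChangePolygon]:
    """Overlay two land-cover epochs and collect change pieces.

    Accepts either two aligned categorical ``Raster`` layers (cell-wise
    comparison, contiguous equal-transition regions merged) or two vector
    layers as lists of ``(shapely geometry, code)`` pairs (geometric
    intersection).  Pieces whose code did not change are labelled none;
    succession classes are assigned by :func:`classify_succession`.
    """
    if isinstance(epoch1, Raster) != isinstance(epoch2, Raster):
        raise TypeError("both epochs must be rasters, or both vector layers")
    if isinstance(epoch1, Raster):
        if epoch1.crs != epoch2.crs:
            raise GridMismatchError("epochs use different CRS")
        pieces = _overlay_rasters(epoch1, epoch2)
    else:
        pieces = _overlay_vectors(list(epoch1), list(epoch2))
    for p in pieces:
        if p.code_from == p.code_to:
            p.change_class = ChangeClass.NONE
        else:
            p.change_class = classify_succession(p.code_from, p.code_to)
    return pieces


def clean_small(
    polygons: list[ChangePolygon], min_area_ha: float = 0.25
) -> list[ChangePolygon]:
    """Drop sliver polygons strictly smaller than ``min_area_ha``.

    The default 0.25 ha removes typical misalignment artifacts; a polygon
    of exactly the minimum area is kept.  Idempotent.
    """
    min_m2 = min_area_ha * 10_000.0
    return [p for p in polygons if p.area_m2 >= min_m2]


def rasterize_changes(
    polygons: list[ChangePolygon], grid: Raster
) -> tuple[Raster, dict[str, float]]:
    """Rasterize classified changes by the cell-centre rule.

    A cell is labelled SS or IS when its centre falls in (or on the
    boundary of) a polygon of that class; unclassified changes and
    unchanged land are "none".  Returns the categorical raster (values
    NONE_VALUE/SS_VALUE/IS_VALUE) and per-class areas in km^2
    (cells x cell area).
    """
    out = np.full(grid.shape, NONE_VALUE, dtype=int)
    X, Y = grid.cell_centers()
    res = grid.resolution
    for p in polygons:
        if p.change_class is ChangeClass.NONE:
            continue
        bx0, by0, bx1, by1 = p.geometry.bounds
        j0 = max(0, int(np.floor((bx0 - grid.xmin) / res)))
        j1 = min(grid.shape[1], int(np.ceil((bx1 - grid.xmin) / res)))
        i0 = max(0, int(np.floor((grid.ymax - by1) / res)))
        i1 = min(grid.shape[0], int(np.ceil((grid.ymax - by0) / res)))
        if i0 >= i1 or j0 >= j1:
            continue
        xs = X[i0:i1, j0:j1].ravel()
        ys = Y[i0:i1, j0:j1].ravel()
        inside = shapely.intersects_xy(p.geometry, xs, ys).reshape(i1 - i0, j1 - j0)
        value = SS_VALUE if p.change_class is ChangeClass.SS else IS_VALUE
        out[i0:i1, j0:j1][inside] = value

    a = grid.cell_area_km2
    areas = {
        "SS": float(np.sum(out == SS_VALUE) * a),
        "IS": float(np.sum(out == IS_VALUE) * a),
        "none": float(np.sum(out == NONE_VALUE) * a),
    }
    return grid.like(out), areas
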