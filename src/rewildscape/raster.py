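"""Shared raster grid abstraction.

All layers in an analysis (categorical land cover, continuous suitability,
density, elevation) live on one axis-aligned square-cell grid in a projected
metric CRS.  ``Raster`` wraps a 2-D numpy array with the grid geometry and
provides the alignment checks every overlay operation relies on.

Row 0 is the northernmost row (image convention); cell (i, j) has its centre
at ``(xmin + (j + 0.5) * res, ymax - (i + 0.5) * res)``.

Persistence uses the ESRI ASCII grid format (plain text, widely readable by
GIS software).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "GridMismatchError", "read_ascii_grid"]


class GridMismatchError(ValueError):
    """Two rasters do not share extent, resolution or CRS."""


@dataclass
class Raster:
    """A single-band raster on an axis-aligned metric grid.

    Parameters
    ----------
    data
        2-D array (rows x cols), row 0 at the top (north).
    xmin, ymax
        Coordinates of the top-left corner of the grid, in metres.
    resolution
        Square cell size in metres.
    nodata
        Value marking invalid cells, or None if all cells are valid.
    crs
        Free-form label for the projected CRS; alignment checks compare it
        for equality only.
    """

    data: np.ndarray
    xmin: float
    ymax: float
    resolution: float
    nodata: float | None = None
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    # -- geometry -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        nrows, ncols = self.data.shape
        return (
            self.xmin,
            self.ymax - nrows * self.resolution,
            self.xmin + ncols * self.resolution,
            self.ymax,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.resolution / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-centre coordinates, shape == data.shape."""
        nrows, ncols = self.data.shape
        xs = self.xmin + (np.arange(ncols) + 0.5) * self.resolution
        ys = self.ymax - (np.arange(nrows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        j = int(np.floor((x - self.xmin) / self.resolution))
        i = int(np.floor((self.ymax - y) / self.resolution))
        nrows, ncols = self.data.shape
        if not (0 <= i < nrows and 0 <= j < ncols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return i, j

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    # -- validity & alignment ------------------------------------------

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            if np.issubdtype(self.data.dtype, np.floating):
                return ~np.isnan(self.data)
            return np.ones(self.data.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isnan(self.data) & (self.data != self.nodata)
        return self.data != self.nodata

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.xmin, other.xmin)
            and np.isclose(self.ymax, other.ymax)
            and np.isclose(self.resolution, other.resolution)
            and self.crs == other.crs
        )

    def require_same_grid(self, other: "Raster", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(f"{what} is not aligned with the reference grid")

    def like(self, data: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster with the same grid geometry and given data."""
        if np.asarray(data).shape != self.data.shape:
            raise GridMismatchError("data shape does not match grid")
        return Raster(
            data=np.asarray(data),
            xmin=self.xmin,
            ymax=self.ymax,
            resolution=self.resolution,
            nodata=nodata,
            crs=self.crs,
        )

    # -- I/O ------------------------------------------------------------

    def write_ascii_grid(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        nrows, ncols = self.data.shape
        nodata = self.nodata if self.nodata is not None else -9999
        yll = self.ymax - nrows * self.resolution
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.xmin}\n"
            f"yllcorner {yll}\n"
            f"cellsize {self.resolution}\n"
            f"NODATA_value {nodata}\n"
        )
        out = np.array(self.data, dtype=float)
        out[~self.valid_mask()] = nodata
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path, crs: str = "local-metric") -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    data = data.reshape(nrows, ncols)
    res = header["cellsize"]
    return Raster(
        data=data,
        xmin=header["xllcorner"],
        ymax=header["yllcorner"] + nrows * res,
        resolution=res,
        nodata=header.get("nodata_value"),
        crs=crs,
    )
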