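"""Gridded single-band rasters and their plain-file serialization.

All layers in one analysis live on a single planar grid (no CRS handling):
``cell_size_km`` gives the edge of a square cell, ``origin`` the (x, y)
coordinate of the *center* of cell (row=0, col=0), with x increasing along
columns and y increasing along rows.  Rasters are written as single-band
float32 TIFF files carrying the grid metadata as JSON in the image
description tag, so they round-trip without any GIS stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band gridded covariate.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Cell values, float; cells equal to ``nodata`` are missing.
    cell_size_km : float
        Edge length of a (square) cell in kilometres.
    origin : tuple of float
        (x, y) of the center of the cell at row 0, col 0.
    nodata : float
        Sentinel marking missing cells.
    """

    values: np.ndarray
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        valid = ~np.isclose(self.values, self.nodata, equal_nan=True)
        valid &= ~np.isnan(self.values)
        return valid

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.allclose(self.origin, other.origin)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + col * self.cell_size_km, y0 + row * self.cell_size_km)


def write_raster(path, raster: RasterGrid) -> None:
    """Write a :class:`RasterGrid` as a single-band float32 TIFF."""
    meta = {
        "cell_size_km": raster.cell_size_km,
        "origin": list(raster.origin),
        "nodata": raster.nodata,
    }
    data = raster.values.astype(np.float32)
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_raster(path) -> RasterGrid:
    """Read a raster previously written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return RasterGrid(
        values=values,
        cell_size_km=float(meta.get("cell_size_km", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=float(meta.get("nodata", DEFAULT_NODATA)),
    )
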