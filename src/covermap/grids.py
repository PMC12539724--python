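"""Minimal co-registered raster model with plain-text persistence.

Every layer in an analysis run shares a single :class:`GridSpec` (shape,
cell size, lower-left origin).  Layers themselves are plain ``numpy``
arrays; no reprojection or resampling is ever performed.  Rasters are
read and written as ESRI ASCII grids, a whitespace text format that any
GIS can open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError

#: Sentinel for missing values in integer rasters.
INT_NODATA = -9999

#: Exact conversion used for all area accounting (1 m^2 in acres).
ACRES_PER_SQ_METER = 0.000247105


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by all co-registered layers of a scene.

    ``x_origin``/``y_origin`` locate the lower-left corner; rows run
    top-down as usual for rasters.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise GridError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_acres(self) -> float:
        """Area of one pixel in acres (0.22239 acres for a 30 m pixel)."""
        return self.pixel_size ** 2 * ACRES_PER_SQ_METER

    def xy(self, row: int, col: int) -> tuple[float, float]:
        """Center coordinates of pixel ``(row, col)``."""
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.pixel_size
        return x, y

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel indices containing point ``(x, y)``; raises if outside."""
        col = int(np.floor((x - self.x_origin) / self.pixel_size))
        row = self.n_rows - 1 - int(np.floor((y - self.y_origin) / self.pixel_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise GridError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def check(self, *arrays: np.ndarray) -> None:
        """Assert that every array matches this grid's shape."""
        for a in arrays:
            if a.shape != self.shape:
                raise GridError(f"array shape {a.shape} != grid shape {self.shape}")


def write_ascii_grid(path, array: np.ndarray, spec: GridSpec,
                     nodata: float | int = INT_NODATA) -> None:
    """Write a single layer as an ESRI ASCII grid (text)."""
    spec.check(array)
    is_int = np.issubdtype(array.dtype, np.integer)
    out = array
    if not is_int:
        out = np.where(np.isnan(array), float(nodata), array)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_origin}\n")
        fh.write(f"yllcorner {spec.y_origin}\n")
        fh.write(f"cellsize {spec.pixel_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.8g"
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path, dtype=None) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns ``(array, spec, nodata)``.

    Float layers get their nodata cells replaced by NaN; integer layers
    keep the sentinel value.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        body = np.loadtxt(fh, ndmin=2)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        pixel_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
    )
    nodata = header.get("nodata_value", INT_NODATA)
    if dtype is not None and np.issubdtype(np.dtype(dtype), np.integer):
        array = body.astype(dtype)
    else:
        array = body.astype(np.float64 if dtype is None else dtype)
        array[array == nodata] = np.nan
    spec.check(array)
    return array, spec, nodata
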