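"""Minimal single-band raster on a regular projected grid.

Rows are stored south-to-north (row 0 is the southernmost row) so that array
indexing matches the residency-grid convention used throughout the package.
ESRI ASCII grid files store rows north-to-south; the I/O functions flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    """A single-band raster anchored at ``(origin_x, origin_y)`` (lower-left corner).

    Cell ``(row, col)`` covers the half-open square
    ``[origin_x + col*s, origin_x + (col+1)*s) x [origin_y + row*s, origin_y + (row+1)*s)``
    with ``s = cell_size`` in metres.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray  # shape (n_rows, n_cols), float; NaN marks no-data
    nodata: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_of(self, x, y):
        """Return (row, col) arrays of the cells containing points.

        Half-open convention; points exactly on the maximum edge of the extent
        belong to the last row/column. Points outside raise ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
            raise ValueError("point outside raster extent")
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def sample(self, x, y):
        """Nearest-cell (containing-cell) sample; NaN where the cell is no-data."""
        row, col = self.cell_of(x, y)
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)


def write_ascii_grid(raster: Raster, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (plain text, readable by GIS tools)."""
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = nodata_value
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x!r}\n"
        f"yllcorner {raster.origin_y!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII rows run north to south
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or a GIS)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    return Raster(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=vals[::-1],
    )
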