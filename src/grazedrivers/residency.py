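"""Gridded livestock residency index (LRI).

The paddock is tiled with square cells (default 5 m). For each hour of a
trial, the number of retained fixes falling in each cell is counted, per
animal or pooled over the treatment's collared animals. The *livestock
residency index* of a cell-hour is that count normalised by the total number
of fixes recorded at that level in the hour, so hourly LRI values sum to one
over the grid and are comparable across hours with different fix dropout.
Raw counts are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from .raster import Raster, write_ascii_grid
from .trajectory import PaddockBoundary, Trajectory, pool_fixes


@dataclass
class GridSpec:
    """Regular square grid over a paddock bounding box.

    The origin (lower-left corner) is snapped *down* to a multiple of
    ``cell_size`` so grids built from the same boundary at nested resolutions
    align. ``mask[row, col]`` is True for cells that intersect the paddock
    polygon; row 0 is the southernmost row.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int
    mask: np.ndarray

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def cell_id(self, row, col):
        """Scalar id ``row * n_cols + col`` for tidy tables."""
        return np.asarray(row) * self.n_cols + np.asarray(col)


def build_grid(boundary: PaddockBoundary, cell_size: float = 5.0) -> GridSpec:
    """Tile the boundary's bounding box with half-open square cells.

    Cells cover ``[x, x+s) x [y, y+s)``. A cell is in the mask iff its closed
    square intersects the paddock polygon (touching the ring counts).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    poly = boundary.polygon
    xmin, ymin, xmax, ymax = poly.bounds
    ox = np.floor(xmin / cell_size) * cell_size
    oy = np.floor(ymin / cell_size) * cell_size
    n_cols = int(np.ceil((xmax - ox) / cell_size))
    n_rows = int(np.ceil((ymax - oy) / cell_size))
    if n_cols == 0 or n_rows == 0:
        raise ValueError("degenerate boundary polygon")

    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x0 = ox + cols * cell_size
    y0 = oy + rows * cell_size
    cells = shapely.box(x0.ravel(), y0.ravel(), x0.ravel() + cell_size, y0.ravel() + cell_size)
    mask = shapely.intersects(poly, cells).reshape(n_rows, n_cols)
    return GridSpec(float(ox), float(oy), float(cell_size), n_cols, n_rows, mask)


def fix_to_cell(easting, northing, spec: GridSpec):
    """Map fix coordinates to (row, col) cell indices (half-open convention).

    Points exactly on the maximum edge of the grid extent belong to the last
    row/column; points outside the extent raise (impossible after cleaning).
    """
    e = np.asarray(easting, dtype=float)
    n = np.asarray(northing, dtype=float)
    xmin, ymin, xmax, ymax = spec.extent
    if np.any((e < xmin) | (e > xmax) | (n < ymin) | (n > ymax)):
        raise ValueError("fix outside grid extent — clean fixes against the boundary first")
    col = np.minimum(np.floor((e - spec.origin_x) / spec.cell_size).astype(int), spec.n_cols - 1)
    row = np.minimum(np.floor((n - spec.origin_y) / spec.cell_size).astype(int), spec.n_rows - 1)
    return row, col


@dataclass
class ResidencyGrid:
    """Hourly and aggregate residency values on a :class:`GridSpec`.

    ``hourly`` is a tidy frame (level_key, hour_index, row, col, count, lri)
    with one row per occupied cell-hour; unoccupied cells are implicitly
    zero and hours with no fixes at all are simply absent (undefined, never
    zero-filled). ``level`` is "animal" or "treatment"; ``level_key`` holds
    the animal id, or the treatment label at treatment level.
    """

    spec: GridSpec
    hourly: pd.DataFrame
    level: str

    def hourly_total(self) -> pd.DataFrame:
        """Total fixes per (level_key, hour)."""
        return (
            self.hourly.groupby(["level_key", "hour_index"], observed=True)["count"]
            .sum()
            .reset_index(name="total")
        )

    def aggregate(self, level_key: str | None = None, how: str = "mean_hourly") -> np.ndarray:
        """Aggregate map over hours for one level key.

        ``mean_hourly`` (default) averages the hourly LRI over hours with at
        least one fix, weighting every hour equally; ``pooled`` recomputes a
        single LRI from the pooled counts.
        """
        df = self.hourly
        if level_key is None:
            keys = df["level_key"].unique()
            if len(keys) != 1:
                raise ValueError(f"specify level_key; grid holds {list(keys)}")
            level_key = keys[0]
        df = df[df["level_key"] == level_key]
        out = np.zeros((self.spec.n_rows, self.spec.n_cols))
        if df.empty:
            return out
        if how == "mean_hourly":
            n_hours = df["hour_index"].nunique()
            np.add.at(out, (df["row"].to_numpy(), df["col"].to_numpy()), df["lri"].to_numpy())
            out /= n_hours
        elif how == "pooled":
            np.add.at(out, (df["row"].to_numpy(), df["col"].to_numpy()), df["count"].to_numpy())
            out /= out.sum()
        else:
            raise ValueError(f"unknown aggregation {how!r}")
        return out


def compute_lri(
    trajs: list[Trajectory],
    spec: GridSpec,
    level: str = "treatment",
    normalize: bool = True,
) -> ResidencyGrid:
    """Count fixes per (cell, hour) and normalise to the residency index.

    At ``level="animal"`` counts are per animal; at ``level="treatment"`` the
    fixes of all collared animals are pooled per treatment. With
    ``normalize=True`` (default) the LRI of a cell-hour is
    ``count / total fixes at that level in that hour``, so for every hour with
    at least one fix the LRI sums to one over cells. ``normalize=False``
    leaves the raw hourly count in the ``lri`` column.
    """
    fixes = pool_fixes(trajs)
    if "hour_index" not in fixes.columns:
        raise ValueError("assign hours before computing residency")
    if fixes.empty:
        return ResidencyGrid(spec, pd.DataFrame(
            columns=["level_key", "hour_index", "row", "col", "count", "lri"]), level)

    if level == "animal":
        fixes["level_key"] = fixes["animal_id"]
    elif level == "treatment":
        fixes["level_key"] = fixes["treatment"].fillna("all")
    else:
        raise ValueError("level must be 'animal' or 'treatment'")

    row, col = fix_to_cell(fixes["easting"].to_numpy(), fixes["northing"].to_numpy(), spec)
    fixes["row"] = row
    fixes["col"] = col
    counts = (
        fixes.groupby(["level_key", "hour_index", "row", "col"], observed=True)
        .size()
        .reset_index(name="count")
    )
    totals = counts.groupby(["level_key", "hour_index"], observed=True)["count"].transform("sum")
    counts["lri"] = counts["count"] / totals if normalize else counts["count"].astype(float)
    return ResidencyGrid(spec, counts, level)


def lri_at_fix(fixes: pd.DataFrame, residency: ResidencyGrid) -> pd.Series:
    """Look up the treatment-level LRI of each fix's cell at the fix's hour.

    This is the model target: one value per retained fix. Fixes in a cell-hour
    with no recorded residency at the grid's level get 0.0 (possible only when
    looking an animal's fixes up in another level's grid); fixes in an hour
    wholly absent from the grid get NaN and should be dropped by the caller
    with a count.
    """
    row, col = fix_to_cell(fixes["easting"].to_numpy(), fixes["northing"].to_numpy(), residency.spec)
    key = pd.DataFrame(
        {
            "level_key": fixes["treatment"].to_numpy()
            if residency.level == "treatment"
            else fixes["animal_id"].to_numpy(),
            "hour_index": fixes["hour_index"].to_numpy(),
            "row": row,
            "col": col,
        }
    )
    merged = key.merge(residency.hourly, how="left", on=["level_key", "hour_index", "row", "col"])
    lri = merged["lri"]
    # distinguish "hour present but cell unvisited" (0) from "hour undefined" (NaN)
    hours_present = set(
        map(tuple, residency.hourly[["level_key", "hour_index"]].drop_duplicates().to_numpy())
    )
    in_known_hour = [
        (lk, h) in hours_present for lk, h in zip(key["level_key"], key["hour_index"])
    ]
    lri = lri.where(~(lri.isna() & pd.Series(in_known_hour)), 0.0)
    lri.index = fixes.index
    return lri


def export_residency(
    residency: ResidencyGrid,
    out_dir: str | Path,
    level_key: str | None = None,
    how: str = "mean_hourly",
) -> tuple[Path, Path]:
    """Write the aggregate LRI map (ESRI ASCII grid) and the tidy hourly table.

    Cells outside the paddock mask are written as no-data. Returns the raster
    and table paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = residency.aggregate(level_key=level_key, how=how)
    vals = np.where(residency.spec.mask, agg, np.nan)
    raster = Raster(residency.spec.origin_x, residency.spec.origin_y, residency.spec.cell_size, vals)
    raster_path = out_dir / "lri_aggregate.asc"
    write_ascii_grid(raster, raster_path)

    table = residency.hourly.copy()
    table["cell_id"] = residency.spec.cell_id(table["row"], table["col"])
    table_path = out_dir / "lri_hourly.csv"
    table[["level_key", "cell_id", "col", "row", "hour_index", "count", "lri"]].to_csv(
        table_path, index=False
    )
    return raster_path, table_path
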