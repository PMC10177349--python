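"""Landscape and weather covariates for the residency driver models.

Each retained fix becomes one model row with twelve predictors:

======  =====================================================================
A       animal identity (categorical, integer-coded)
EA, NO  easting / northing of the fix (m) — absorb residual spatial structure
NT      near distance to the closest tree (m)
NW      near distance to the closest water trough (m)
NF      near distance to the closest fence line (m)
NDVI    normalised difference vegetation index at the fix (pasture greenness)
AS      terrain aspect at the fix (degrees, 0 = north, clockwise)
EL      elevation at the fix (m ASL)
T       air temperature of the fix's hour (°C)
R       rainfall of the fix's hour (mm)
WC      sheep chill index of the fix's hour (kJ m⁻² h⁻¹)
======  =====================================================================

The target is the treatment-level livestock residency index of the fix's
cell-hour (:func:`grazedrivers.residency.lri_at_fix`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, MultiLineString, MultiPoint

from .raster import Raster
from .residency import GridSpec, ResidencyGrid, lri_at_fix
from .trajectory import PaddockBoundary, Trajectory, pool_fixes

#: fixed predictor order of the model table
PREDICTORS = ["A", "EA", "NO", "NT", "NW", "NF", "NDVI", "AS", "EL", "T", "R", "WC"]


@dataclass
class LandscapeFeatures:
    """Vector and raster layers of one paddock, all in a single projected CRS."""

    boundary: PaddockBoundary
    trees: np.ndarray  # (n, 2) easting/northing
    troughs: np.ndarray  # (n, 2)
    fences: Sequence[LineString] | None  # None -> boundary edges serve as fences
    elevation: Raster
    ndvi: Raster

    def fence_lines(self) -> MultiLineString:
        if self.fences is not None and len(self.fences) > 0:
            return MultiLineString([LineString(f) for f in self.fences])
        return MultiLineString([LineString(self.boundary.polygon.exterior.coords)])


def near_distance(easting, northing, features) -> np.ndarray:
    """Minimum Euclidean distance (m) from points to a feature set.

    ``features`` may be an ``(n, 2)`` array of points, a sequence of shapely
    geometries, or a single shapely geometry. Point-to-polyline distance is
    point-to-nearest-segment.
    """
    pts = shapely.points(np.asarray(easting, dtype=float), np.asarray(northing, dtype=float))
    if isinstance(features, np.ndarray) or (
        isinstance(features, (list, tuple))
        and len(features)
        and not isinstance(features[0], shapely.Geometry)
    ):
        arr = np.asarray(features, dtype=float)
        if arr.size == 0:
            raise ValueError("empty feature set")
        geom = MultiPoint(arr.reshape(-1, 2))
    elif isinstance(features, shapely.Geometry):
        if features.is_empty:
            raise ValueError("empty feature set")
        geom = features
    else:
        feats = list(features)
        if not feats:
            raise ValueError("empty feature set")
        geom = shapely.union_all(feats)
    return shapely.distance(geom, pts)


def sample_raster(easting, northing, raster: Raster) -> np.ndarray:
    """Value of the raster cell containing each point (NaN where no-data)."""
    return raster.sample(easting, northing)


def compute_aspect(elevation: Raster, flat_tol: float = 1e-6) -> Raster:
    """Terrain aspect from a DEM: downslope azimuth, 0° = north, clockwise.

    Gradients use Horn's eight-neighbour weighted finite differences, the
    standard GIS stencil; edge cells get a replicated-border neighbourhood so
    fence-adjacent cells keep an aspect. Cells whose gradient magnitude falls
    below ``flat_tol`` (m per m) are flat and carry NaN.
    """
    if elevation.values.shape[0] < 3 or elevation.values.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3 for aspect")
    z = np.pad(elevation.values, 1, mode="edge")
    s = elevation.cell_size
    # row index increases northward; "north" neighbours are at row+1
    zN, zS = z[2:, 1:-1], z[:-2, 1:-1]
    zE, zW = z[1:-1, 2:], z[1:-1, :-2]
    zNE, zNW = z[2:, 2:], z[2:, :-2]
    zSE, zSW = z[:-2, 2:], z[:-2, :-2]
    dzdx = ((zNE + 2 * zE + zSE) - (zNW + 2 * zW + zSW)) / (8 * s)
    dzdy = ((zNE + 2 * zN + zNW) - (zSE + 2 * zS + zSW)) / (8 * s)
    grad = np.hypot(dzdx, dzdy)
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[~(grad >= flat_tol)] = np.nan
    return Raster(elevation.origin_x, elevation.origin_y, s, aspect)


def interpolate_ndvi(
    samples: pd.DataFrame,
    spec: GridSpec,
    power: float = 2.0,
    k: int | None = None,
    snap_tol: float = 1e-9,
) -> Raster:
    """Inverse-distance-weighted NDVI surface on the residency grid.

    ``samples`` has columns ``easting, northing, ndvi`` (e.g. transect
    readings). Each masked-in cell centre gets the IDW estimate
    ``Σ w_i v_i / Σ w_i`` with ``w_i = d_i^-power`` over all samples (or the
    ``k`` nearest when given). A cell centre within ``snap_tol`` of a sample
    returns that sample's value exactly. Cells outside the paddock mask are
    NaN.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 NDVI samples to interpolate")
    pts = samples[["easting", "northing"]].to_numpy(dtype=float)
    vals = samples["ndvi"].to_numpy(dtype=float)

    s = spec.cell_size
    xs = spec.origin_x + (np.arange(spec.n_cols) + 0.5) * s
    ys = spec.origin_y + (np.arange(spec.n_rows) + 0.5) * s
    X, Y = np.meshgrid(xs, ys)
    centers = np.column_stack([X.ravel(), Y.ravel()])

    d = cdist(centers, pts)
    if k is not None:
        kth = np.argsort(d, axis=1)[:, :k]
        dk = np.take_along_axis(d, kth, axis=1)
        vk = vals[kth]
    else:
        dk, vk = d, np.broadcast_to(vals, d.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = dk ** (-power)
        est = np.einsum("ij,ij->i", w, vk) / w.sum(axis=1)

    exact = dk.min(axis=1) <= snap_tol
    if exact.any():
        est[exact] = vk[np.arange(len(centers)), dk.argmin(axis=1)][exact]

    out = est.reshape(spec.n_rows, spec.n_cols)
    out = np.where(spec.mask, out, np.nan)
    return Raster(spec.origin_x, spec.origin_y, s, out)


def wind_chill(temperature, wind_speed, rainfall):
    """Sheep chill index (kJ m⁻² h⁻¹) combining cold, wind and rain stress.

    ``C = (11.7 + 3.1 v^0.5)(40 - T) + 481 + 418(1 - e^(-0.04 R))`` with
    temperature T in °C, wind speed v in m/s and rainfall R in mm/h. The
    first term is convective loss down the body-to-air temperature gradient
    (40 °C core), the constant is basal radiative loss, and the saturating
    rain term models evaporative loss from a wet fleece.
    """
    T = np.asarray(temperature, dtype=float)
    v = np.asarray(wind_speed, dtype=float)
    R = np.asarray(rainfall, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(v)) and np.all(np.isfinite(R))):
        raise ValueError("wind chill inputs must be finite")
    if np.any(v < 0) or np.any(R < 0):
        raise ValueError("wind speed and rainfall must be nonnegative")
    return (11.7 + 3.1 * np.sqrt(v)) * (40.0 - T) + 481.0 + 418.0 * (1.0 - np.exp(-0.04 * R))


def join_weather(rows: pd.DataFrame, weather: pd.DataFrame) -> pd.DataFrame:
    """Attach hourly T, R and WC to timestamped rows (floor-to-hour join).

    ``weather`` has columns ``timestamp, temp_c, rain_mm, wind_ms`` at hourly
    resolution. Every row hour must be covered; gaps raise with the missing
    hours listed.
    """
    w = weather.copy()
    w["hour"] = pd.to_datetime(w["timestamp"], utc=True).dt.floor("h")
    if w["hour"].duplicated().any():
        raise ValueError("duplicate hours in weather series")
    out = rows.copy()
    out["_hour"] = pd.to_datetime(out["timestamp"], utc=True).dt.floor("h")
    merged = out.merge(
        w[["hour", "temp_c", "rain_mm", "wind_ms"]], left_on="_hour", right_on="hour", how="left"
    )
    gaps = merged.loc[merged["temp_c"].isna(), "_hour"].unique()
    if len(gaps):
        raise ValueError(f"weather series does not cover hours: {sorted(gaps)[:10]}")
    merged["T"] = merged["temp_c"]
    merged["R"] = merged["rain_mm"]
    merged["WC"] = wind_chill(merged["temp_c"], merged["wind_ms"], merged["rain_mm"])
    return merged.drop(columns=["_hour", "hour", "temp_c", "rain_mm", "wind_ms"]).set_index(
        rows.index
    )


def vif_filter(
    table: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative collinearity screen by variance inflation factor.

    ``VIF_j = 1/(1 - R²_j)`` where ``R²_j`` comes from an OLS regression (with
    intercept) of column ``j`` on the remaining columns. While the largest VIF
    exceeds ``threshold`` that column is dropped; ties break by column-name
    order so the screen is deterministic. Returns the retained column names
    and a tidy log of every round's VIFs.

    Perfectly collinear columns have infinite VIF and fall first; a constant
    column is an error (its VIF is undefined).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two columns for a VIF screen")
    X = table.to_numpy(dtype=float)
    if len(X) <= len(cols):
        raise ValueError("need more rows than columns for a VIF screen")
    if np.any(np.nanstd(X, axis=0) == 0):
        const = [c for c, s in zip(cols, np.nanstd(X, axis=0)) if s == 0]
        raise ValueError(f"constant columns have undefined VIF: {const}")

    def vif_of(active: list[str]) -> pd.Series:
        out = {}
        for c in active:
            others = [o for o in active if o != c]
            y = table[c].to_numpy(dtype=float)
            Xo = sm.add_constant(table[others].to_numpy(dtype=float))
            r2 = sm.OLS(y, Xo).fit().rsquared
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    active = sorted(cols)
    log = []
    round_no = 0
    while len(active) >= 2:
        vifs = vif_of(active)
        log.append(vifs.rename_axis("column").reset_index(name="vif").assign(round=round_no))
        if vifs.max() <= threshold:
            break
        # max VIF; ties resolved by name order (active is kept sorted)
        drop = vifs[vifs == vifs.max()].index[0]
        active = [c for c in active if c != drop]
        round_no += 1
    retained = [c for c in cols if c in active]
    return retained, pd.concat(log, ignore_index=True)


def assemble_model_table(
    trajs: list[Trajectory],
    residency: ResidencyGrid,
    landscape: LandscapeFeatures,
    weather: pd.DataFrame,
    aspect: Raster | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-fix model table: 12 predictors + ``lri`` target.

    One row per retained fix. Rows whose NDVI or elevation falls on a no-data
    cell, whose aspect is flat/undefined, or whose hour has no defined
    residency are dropped; the returned report counts drops per cause.
    Animal identity is integer-coded with the level order recorded in the
    report (forests treat it as an unordered categorical).
    """
    fixes = pool_fixes(trajs)
    if fixes.empty:
        raise ValueError("no fixes to assemble")
    if aspect is None:
        aspect = compute_aspect(landscape.elevation)

    tab = pd.DataFrame(index=fixes.index)
    animal_levels = sorted(fixes["animal_id"].unique())
    tab["A"] = pd.Categorical(fixes["animal_id"], categories=animal_levels).codes
    tab["EA"] = fixes["easting"].to_numpy()
    tab["NO"] = fixes["northing"].to_numpy()
    e, n = fixes["easting"].to_numpy(), fixes["northing"].to_numpy()
    tab["NT"] = near_distance(e, n, landscape.trees)
    tab["NW"] = near_distance(e, n, landscape.troughs)
    tab["NF"] = near_distance(e, n, landscape.fence_lines())
    tab["NDVI"] = sample_raster(e, n, landscape.ndvi)
    tab["AS"] = sample_raster(e, n, aspect)
    tab["EL"] = sample_raster(e, n, landscape.elevation)
    wx = join_weather(fixes[["timestamp"]], weather)
    tab[["T", "R", "WC"]] = wx[["T", "R", "WC"]]
    tab["lri"] = lri_at_fix(fixes, residency)
    tab["timestamp"] = fixes["timestamp"].to_numpy()
    tab["hour_index"] = fixes["hour_index"].to_numpy()

    report = {
        "n_fixes": len(tab),
        "animal_levels": animal_levels,
        "dropped_no_ndvi": int(tab["NDVI"].isna().sum()),
        "dropped_no_elevation": int(tab["EL"].isna().sum()),
        "dropped_flat_aspect": int(tab["AS"].isna().sum()),
        "dropped_undefined_lri": int(tab["lri"].isna().sum()),
    }
    keep = tab[PREDICTORS + ["lri"]].notna().all(axis=1)
    tab = tab[keep].reset_index(drop=True)
    report["n_rows"] = len(tab)
    return tab, report
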