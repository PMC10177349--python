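"""On-disk formats: fix CSV, landscape GeoJSON layers, ASCII rasters, weather CSV.

All outputs are plain text. Geometries are GeoJSON in a projected CRS (metre
units); the CRS code is carried in a top-level ``crs_epsg`` property and is
purely declarative — no reprojection happens in this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape

from .covariates import LandscapeFeatures
from .raster import read_ascii_grid, write_ascii_grid
from .trajectory import PaddockBoundary


def write_fixes_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    """Write a raw fix table with the canonical on-disk headers."""
    out = fixes.rename(
        columns={"easting": "easting_m", "northing": "northing_m", "ttf": "ttf_s"}
    )
    out.to_csv(path, index=False)


def write_weather_csv(weather: pd.DataFrame, path: str | Path) -> None:
    weather.to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def _feature(geom, **props) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_landscape(landscape: LandscapeFeatures, out_dir: str | Path,
                    crs_epsg: int | None = None) -> None:
    """Write boundary/trees/troughs/fences GeoJSON plus elevation/NDVI grids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from shapely.geometry import Point

    layers = {
        "boundary": [_feature(landscape.boundary.polygon, name=landscape.boundary.name)],
        "trees": [_feature(Point(xy)) for xy in np.atleast_2d(landscape.trees)],
        "troughs": [_feature(Point(xy)) for xy in np.atleast_2d(landscape.troughs)],
        "fences": [_feature(f) for f in (landscape.fences or [])]
        or [_feature(LineString(landscape.boundary.polygon.exterior.coords))],
    }
    for name, feats in layers.items():
        doc = {"type": "FeatureCollection", "features": feats}
        if crs_epsg is not None:
            doc["crs_epsg"] = crs_epsg
        (out_dir / f"{name}.geojson").write_text(json.dumps(doc))
    write_ascii_grid(landscape.elevation, out_dir / "elevation.asc")
    write_ascii_grid(landscape.ndvi, out_dir / "ndvi.asc")


def read_landscape(in_dir: str | Path) -> LandscapeFeatures:
    """Read the layers written by :func:`write_landscape`."""
    in_dir = Path(in_dir)

    def geoms(name):
        doc = json.loads((in_dir / f"{name}.geojson").read_text())
        return [shape(f["geometry"]) for f in doc["features"]]

    boundary_geom = geoms("boundary")[0]
    if not isinstance(boundary_geom, Polygon):
        raise ValueError("boundary layer must contain a polygon")
    trees = np.array([[g.x, g.y] for g in geoms("trees")])
    troughs = np.array([[g.x, g.y] for g in geoms("troughs")])
    fences = [g for g in geoms("fences")]
    return LandscapeFeatures(
        boundary=PaddockBoundary(boundary_geom),
        trees=trees,
        troughs=troughs,
        fences=fences,
        elevation=read_ascii_grid(in_dir / "elevation.asc"),
        ndvi=read_ascii_grid(in_dir / "ndvi.asc"),
    )
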