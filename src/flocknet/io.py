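"""Reading and writing the pipeline's file formats.

Fixes and weather travel as CSV, shade patches as a GeoJSON
FeatureCollection of polygons, generating truth as JSON.  Coordinates are
planar metres in a local paddock frame; a local equirectangular projection
converts to and from lon/lat, which is adequate at the 6 × 1 km scale where
Earth curvature is negligible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .environment import ShadePatch

__all__ = [
    "LocalProjection",
    "write_fixes_csv",
    "read_fixes_csv",
    "write_weather_csv",
    "read_weather_csv",
    "write_patches_geojson",
    "read_patches_geojson",
    "write_truth_json",
    "read_truth_json",
]

_M_PER_DEG_LAT = 111_320.0


class LocalProjection:
    """Equirectangular lon/lat <-> local metres around a reference point."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = lon0
        self.lat0 = lat0
        self._mx = _M_PER_DEG_LAT * np.cos(np.radians(lat0))

    def to_local(self, lon, lat):
        x = (np.asarray(lon) - self.lon0) * self._mx
        y = (np.asarray(lat) - self.lat0) * _M_PER_DEG_LAT
        return x, y

    def to_lonlat(self, x, y):
        lon = self.lon0 + np.asarray(x) / self._mx
        lat = self.lat0 + np.asarray(y) / _M_PER_DEG_LAT
        return lon, lat


#: Default reference: south-west corner of an arid-zone paddock frame.
DEFAULT_PROJECTION = LocalProjection(lon0=141.70, lat0=-31.09)


def write_fixes_csv(fixes: pd.DataFrame, path,
                    projection: LocalProjection = DEFAULT_PROJECTION) -> None:
    out = fixes.copy()
    lon, lat = projection.to_lonlat(out["x"].to_numpy(), out["y"].to_numpy())
    out["lon"] = np.round(lon, 8)
    out["lat"] = np.round(lat, 8)
    cols = ["id", "time", "x", "y", "lon", "lat", "nsat"]
    if "artifact" in out.columns:
        cols.append("artifact")
    out[cols].rename(columns={"x": "x_m", "y": "y_m"}).to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    df = df.rename(columns={"x_m": "x", "y_m": "y"})
    return df


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_patches_geojson(patches, path) -> None:
    features = []
    for p in patches:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {"patch_id": p.patch_id, "height": p.height},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_patches_geojson(path) -> list[ShadePatch]:
    data = json.loads(Path(path).read_text())
    patches = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        patches.append(
            ShadePatch(
                patch_id=str(props.get("patch_id", f"patch_{len(patches)}")),
                polygon=shape(feat["geometry"]),
                height=props.get("height"),
            )
        )
    return patches


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, sort_keys=True, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
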