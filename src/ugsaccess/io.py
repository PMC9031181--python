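"""Reading, filtering and writing the pipeline's file formats.

Communities arrive as CSV (id, lon, lat, households, price, city_id;
column names remappable). Rows failing the attribute-completeness
filter — any required field missing or non-numeric — are dropped with a
warning, mirroring how listing data are cleaned. Green spaces arrive as
GeoJSON (Point or Polygon features) or CSV; polygons are reduced to
centroid plus area, and spots smaller than 1 ha (inclusive boundary:
exactly 1 ha is kept) are filtered out. Results are written as plain
CSVs with a fixed column order so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from .spatial import EARTH_RADIUS_M
from .types import Community, GreenSpace, RunConfig

DEFAULT_COLUMNS = {
    "id": "id",
    "lon": "lon",
    "lat": "lat",
    "households": "households",
    "price": "price",
    "city_id": "city_id",
}


class FormatError(ValueError):
    """A file is structurally unusable (missing required columns)."""


def read_communities(
    path: str | Path, column_map: dict | None = None
) -> tuple[list[Community], int]:
    """Read demand points from CSV, keeping only attribute-complete rows.

    Returns ``(communities, n_dropped)``. A missing required column is
    fatal; individual rows with missing or non-numeric households/price
    or coordinates are dropped with a warning. ``city_id`` is optional
    and defaults to ``"city"``.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, dtype={cols["id"]: str})
    required = ["id", "lon", "lat", "households", "price"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_city = cols["city_id"] in df.columns

    out: list[Community] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            lon = float(row[cols["lon"]])
            lat = float(row[cols["lat"]])
            hh_raw = float(row[cols["households"]])
            price = float(row[cols["price"]])
            if any(np.isnan(v) for v in (lon, lat, hh_raw, price)):
                raise ValueError("missing value")
            if hh_raw != int(hh_raw):
                raise ValueError("non-integer households")
            city = str(row[cols["city_id"]]) if has_city else "city"
            if has_city and (city == "nan" or city == ""):
                raise ValueError("missing city_id")
            out.append(
                Community(
                    id=str(row[cols["id"]]),
                    lon=lon,
                    lat=lat,
                    households=int(hh_raw),
                    price=price,
                    city_id=city,
                )
            )
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            warnings.warn(f"{path}: dropped community row ({exc})")
    return out, n_dropped


def _polygon_area_m2(geom, planar: bool) -> float:
    if planar:
        return geom.area
    # local equirectangular projection about the centroid latitude
    lat0 = np.radians(geom.centroid.y)
    import shapely.ops

    proj = shapely.ops.transform(
        lambda x, y: (
            np.radians(x) * EARTH_RADIUS_M * np.cos(lat0),
            np.radians(y) * EARTH_RADIUS_M,
        ),
        geom,
    )
    return proj.area


def read_greenspaces(
    path: str | Path,
    min_area_ha: float = 1.0,
    area_unit: str = "m2",
    planar: bool = False,
    column_map: dict | None = None,
) -> tuple[list[GreenSpace], int]:
    """Read supply points from GeoJSON or CSV; filter spots < ``min_area_ha``.

    GeoJSON features may be Points (area taken from an ``area_ha`` or
    ``area_m2`` property) or Polygons (area from geometry unless a
    property overrides it; centroid used as the spot location).
    CSV needs columns id, lon, lat, area (unit per ``area_unit``:
    ``"m2"`` or ``"ha"``) and optionally city_id.

    Returns ``(greenspaces, n_dropped)`` where dropped counts both
    unresolvable rows and spots below the area threshold (the exactly-
    ``min_area_ha`` boundary is inclusive — such spots are kept).
    """
    path = Path(path)
    raw: list[tuple[str, float, float, float, str]] = []  # id, lon, lat, m2, city
    n_dropped = 0
    if path.suffix.lower() in (".geojson", ".json"):
        data = json.loads(path.read_text())
        features = data.get("features", [])
        for k, feat in enumerate(features):
            props = feat.get("properties") or {}
            fid = str(props.get("id", f"feature-{k}"))
            city = str(props.get("city_id", "city"))
            try:
                geom = shape(feat["geometry"])
                if "area_m2" in props:
                    area_m2 = float(props["area_m2"])
                elif "area_ha" in props:
                    area_m2 = float(props["area_ha"]) * 10_000.0
                elif geom.geom_type in ("Polygon", "MultiPolygon"):
                    area_m2 = _polygon_area_m2(geom, planar)
                else:
                    raise ValueError("point feature without an area property")
                c = geom.centroid
                raw.append((fid, float(c.x), float(c.y), area_m2, city))
            except (KeyError, ValueError, TypeError) as exc:
                n_dropped += 1
                warnings.warn(f"{path}: dropped green-space feature {fid} ({exc})")
    else:
        cols = {"id": "id", "lon": "lon", "lat": "lat", "area": "area",
                "city_id": "city_id", **(column_map or {})}
        df = pd.read_csv(path, dtype={cols["id"]: str})
        missing = [cols[k] for k in ("id", "lon", "lat", "area") if cols[k] not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        factor = 10_000.0 if area_unit == "ha" else 1.0
        has_city = cols["city_id"] in df.columns
        for _, row in df.iterrows():
            fid = str(row[cols["id"]])
            try:
                lon, lat = float(row[cols["lon"]]), float(row[cols["lat"]])
                area_m2 = float(row[cols["area"]]) * factor
                if any(np.isnan(v) for v in (lon, lat, area_m2)):
                    raise ValueError("missing value")
                city = str(row[cols["city_id"]]) if has_city else "city"
                raw.append((fid, lon, lat, area_m2, city))
            except (ValueError, TypeError) as exc:
                n_dropped += 1
                warnings.warn(f"{path}: dropped green-space row {fid} ({exc})")

    out: list[GreenSpace] = []
    min_m2 = min_area_ha * 10_000.0
    for fid, lon, lat, area_m2, city in raw:
        if area_m2 >= min_m2:
            out.append(GreenSpace(id=fid, lon=lon, lat=lat, area_m2=area_m2, city_id=city))
        else:
            n_dropped += 1
    return out, n_dropped


def write_communities_csv(communities: Sequence[Community], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.id, c.lon, c.lat, c.households, c.price, c.city_id) for c in communities],
        columns=["id", "lon", "lat", "households", "price", "city_id"],
    )
    df.to_csv(path, index=False)


def write_greenspaces_csv(greenspaces: Sequence[GreenSpace], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.id, g.lon, g.lat, g.area_m2, g.city_id) for g in greenspaces],
        columns=["id", "lon", "lat", "area", "city_id"],
    )
    df.to_csv(path, index=False)


def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a pipeline result as CSVs with deterministic column order.

    Emits per_community.csv, per_city.csv, ttests.csv and
    tier_regression.csv under ``out_dir``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("per_community", result.per_community),
        ("per_city", result.per_city),
        ("ttests", result.ttests),
        ("tier_regression", result.tier_regressions),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**data)
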