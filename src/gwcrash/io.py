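"""Readers and writers for spatial unit tables.

Supported input formats: GeoJSON (polygon features with attribute
properties) and CSV (attributes plus planar ``x``/``y`` centroid columns).
Coordinates must be in a projected CRS — inputs that look like lon/lat
degrees are rejected because kernel and contiguity computations assume
Euclidean metric distance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .types import GWCrashError, SpatialUnitTable

log = logging.getLogger("gwcrash")


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    """Heuristic lon/lat detector.

    Degrees sit inside the +-180 x +-90 box and essentially always carry
    fractional parts; projected planar coordinates are either large
    (metres) or exactly on grid ticks.
    """
    in_box = bool(np.all(np.abs(x) <= 180) and np.all(np.abs(y) <= 90))
    fractional = bool(
        np.any(x != np.round(x)) or np.any(y != np.round(y))
    )
    return in_box and fractional


def _drop_missing(df: pd.DataFrame, used: Sequence[str]) -> pd.DataFrame:
    used = [c for c in used if c in df.columns]
    before = len(df)
    out = df.dropna(subset=used)
    dropped = before - len(out)
    if dropped:
        log.warning("dropped %d row(s) with missing values in %s", dropped, used)
    return out


def read_spatial_table(
    path,
    fmt: Optional[str] = None,
    response: Optional[str] = None,
    covariates: Optional[Sequence[str]] = None,
    offset: Optional[str] = None,
    id_column: Optional[str] = None,
    crs: Optional[str] = None,
    allow_geographic: bool = False,
) -> SpatialUnitTable:
    """Load a zonal table from GeoJSON or CSV.

    Rows with missing values in any used column are dropped (with a
    logged count).  For GeoJSON, centroids are computed from the
    geometry when ``x``/``y`` attributes are absent.
    """
    path = Path(path)
    if not path.exists():
        raise GWCrashError(f"input file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".geojson": "geojson", ".json": "geojson", ".csv": "csv"}.get(suffix)
        if fmt is None:
            raise GWCrashError(f"cannot infer format from suffix {suffix!r}")
    fmt = fmt.lower()
    if fmt in ("shp", "shapefile"):
        raise GWCrashError(
            "ESRI Shapefile input is not supported by this build; "
            "convert to GeoJSON or CSV"
        )

    geometry = None
    if fmt == "csv":
        df = pd.read_csv(path)
        if not {"x", "y"}.issubset(df.columns):
            raise GWCrashError("CSV input requires 'x' and 'y' centroid columns")
    elif fmt == "geojson":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise GWCrashError("GeoJSON input must be a FeatureCollection")
        records, geometry = [], []
        for feat in gj["features"]:
            records.append(dict(feat.get("properties") or {}))
            geometry.append(shape(feat["geometry"]) if feat.get("geometry") else None)
        df = pd.DataFrame.from_records(records)
        if not {"x", "y"}.issubset(df.columns):
            if any(g is None for g in geometry):
                raise GWCrashError("features without geometry and without x/y attributes")
            cent = [g.centroid for g in geometry]
            df["x"] = [c.x for c in cent]
            df["y"] = [c.y for c in cent]
    else:
        raise GWCrashError(f"unknown format {fmt!r}")

    used = ["x", "y"] + [c for c in [response, offset] if c] + list(covariates or [])
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise GWCrashError(f"missing required columns: {missing_cols}")
    keep = df[used].notna().all(axis=1)
    if geometry is not None:
        geometry = [g for g, k in zip(geometry, keep) if k]
    df = _drop_missing(df, used)

    if id_column is not None:
        df = df.set_index(id_column)
    elif "unit_id" in df.columns:
        df = df.set_index("unit_id")
    else:
        df.index = pd.Index([f"u{k:04d}" for k in range(len(df))], name="unit_id")

    x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    if not allow_geographic and _looks_geographic(x, y):
        raise GWCrashError(
            "coordinates look like lon/lat degrees; re-project the data to a "
            "planar CRS (Euclidean distances are assumed)"
        )
    return SpatialUnitTable(
        data=df,
        response=response,
        covariates=list(covariates or []),
        offset=offset,
        geometry=geometry,
        crs=crs,
    )


def write_geojson(
    units: SpatialUnitTable, path, properties: Optional[pd.DataFrame] = None
) -> None:
    """Write units (and optional extra per-unit properties) as GeoJSON."""
    from shapely.geometry import Point

    feats = []
    extra = properties if properties is not None else pd.DataFrame(index=units.unit_ids)
    for i, uid in enumerate(units.unit_ids):
        geom = (
            units.geometry[i]
            if units.geometry is not None
            else Point(units.data["x"].iloc[i], units.data["y"].iloc[i])
        )
        props = {"unit_id": str(uid)}
        props.update({k: _jsonable(v) for k, v in units.data.iloc[i].items()})
        if uid in extra.index:
            props.update({k: _jsonable(v) for k, v in extra.loc[uid].items()})
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def write_units_csv(units: SpatialUnitTable, path) -> None:
    units.data.to_csv(path, index_label="unit_id")
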