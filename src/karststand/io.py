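"""Readers and writers for stem maps, substrate maps, elevations and tables.

All coordinates are plot-local Cartesian metres (x east, y north,
origin at the lower-left plot corner); GeoJSON files carry the same
local frame and are explicitly non-geographic. CSV files are
comma-separated, UTF-8, '.' decimal, header mandatory; numeric output
uses 9 significant digits so reruns diff cleanly. Tables are written
with a leading ``# provenance:`` comment line which pandas readers
skip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import mapping, shape

from .terrain import SubstrateMap

STEM_COLUMNS = ["id", "x", "y", "species", "dbh_cm", "th_m", "lifeform"]
FLOAT_FMT = "%.9g"


class IOValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Stem maps


def read_stem_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise IOValidationError(f"stem map {path}: missing columns {missing}")
    for c in ("x", "y", "dbh_cm", "th_m"):
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            raise IOValidationError(
                f"stem map {path}: non-numeric {c} at rows {df.index[bad].tolist()}"
            )
        df[c] = pd.to_numeric(df[c])
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise IOValidationError(f"stem map {path}: duplicate ids {dup.unique().tolist()}")
    dup_xy = df.duplicated(subset=["x", "y"])
    if dup_xy.any():
        raise IOValidationError(
            f"stem map {path}: duplicate coordinates at rows {df.index[dup_xy].tolist()}"
        )
    small = df["dbh_cm"] < 1.0
    if small.any():
        raise IOValidationError(
            f"stem map {path}: DBH below 1 cm at rows {df.index[small].tolist()}"
        )
    return df[STEM_COLUMNS]


def write_stem_map(stems: pd.DataFrame, path, provenance: str = "") -> None:
    _write_table(stems[STEM_COLUMNS], path, provenance)


# ---------------------------------------------------------------------------
# Substrate maps


def read_substrate(path, plot_width: float, plot_height: float) -> SubstrateMap:
    """Rock polygons from GeoJSON (FeatureCollection) or a WKT list."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    polys = []
    if path.suffix.lower() in {".geojson", ".json"} or text.lstrip().startswith("{"):
        data = json.loads(text)
        for i, feat in enumerate(data.get("features", [])):
            try:
                geom = shape(feat["geometry"])
            except Exception as e:
                raise IOValidationError(f"substrate {path}: bad geometry at feature {i}: {e}")
            if not geom.is_valid:
                raise IOValidationError(f"substrate {path}: invalid geometry at feature {i}")
            polys.append(geom)
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            geom = shapely_wkt.loads(line)
            if not geom.is_valid:
                raise IOValidationError(f"substrate {path}: invalid geometry at line {i}")
            polys.append(geom)
    return SubstrateMap(polys, plot_width, plot_height)


def _round_coords(obj, ndigits=6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def write_substrate_geojson(substrate: SubstrateMap, path) -> None:
    features = []
    for poly in substrate.polygons:
        geom = mapping(poly)
        geom = {
            "type": geom["type"],
            "coordinates": _round_coords(geom["coordinates"]),
        }
        features.append(
            {"type": "Feature", "properties": {"substrate": "rock"}, "geometry": geom}
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": "plot-local metres, non-geographic",
        "plot_width": substrate.plot_width,
        "plot_height": substrate.plot_height,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Elevations and generic tables


def read_elevations(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    needed = ["kind", "i", "j", "x", "y", "z"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise IOValidationError(f"elevation table {path}: missing columns {missing}")
    return df[needed]


def write_elevations(elev: pd.DataFrame, path, provenance: str = "") -> None:
    _write_table(elev, path, provenance)


def _write_table(df: pd.DataFrame, path, provenance: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path, provenance: str = "") -> None:
    """Write a metric table with a provenance comment header."""
    _write_table(df, path, provenance)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_config(path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
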