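"""Readers and writers for the pipeline's file formats.

Rasters travel as ESRI ASCII grids (plain text, readable by any GIS),
vectors as GeoJSON, tables as CSV and configuration as YAML. Every
writer has a matching reader and round-trips losslessly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catchments import CatchmentClass, CatchmentRule
from .cost import SpeedConfig
from .facilities import SIGNAL_FUNCTIONS, FacilityRecord
from .grid import GridSpec
from .synthetic import RoadSegment

NODATA = -9999.0


# ---------------------------------------------------------------------------
# Rasters: ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    arr = np.where(np.isfinite(array), array, NODATA)
    header = (
        f"ncols {grid.cols}\nnrows {grid.rows}\n"
        f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    grid = GridSpec(cell_size=header["cellsize"], x0=header["xllcorner"],
                    y0=header["yllcorner"], rows=int(header["nrows"]),
                    cols=int(header["ncols"]))
    nodata = header["nodata_value"]
    arr = np.where(arr == nodata, np.inf, arr)
    if arr.shape != grid.shape:
        raise ValueError(f"{path}: data shape {arr.shape} does not match header")
    return arr, grid


# ---------------------------------------------------------------------------
# Facility rosters: CSV and GeoJSON
# ---------------------------------------------------------------------------

_BOOL_COLS = ["open_24_7", "has_electricity", "has_water", "has_transport",
              "has_communication", "caesarean_last_3_months"]


def facilities_to_frame(facilities: list[FacilityRecord]) -> pd.DataFrame:
    rows = []
    for f in facilities:
        row = {"id": f.id, "x": f.x, "y": f.y}
        for col in _BOOL_COLS:
            row[col] = int(getattr(f, col))
        for i, fn in enumerate(SIGNAL_FUNCTIONS):
            row[f"staffed_{fn}"] = int(f.signal_staffed[i])
            row[f"equipped_{fn}"] = int(f.signal_equipped[i])
        row["sector"] = f.sector
        row["facility_type"] = f.facility_type
        row["readiness_score"] = f.readiness_score
        row["level"] = f.level
        rows.append(row)
    return pd.DataFrame(rows)


def write_facilities_csv(facilities: list[FacilityRecord],
                         path: str | Path) -> None:
    facilities_to_frame(facilities).to_csv(path, index=False)


def read_facilities_csv(path: str | Path) -> list[FacilityRecord]:
    df = pd.read_csv(path)
    required = {"id", "x", "y", *_BOOL_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing facility columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(id=str(row["id"]), x=float(row["x"]), y=float(row["y"]))
        for col in _BOOL_COLS:
            kwargs[col] = bool(row[col])
        kwargs["signal_staffed"] = tuple(
            bool(row[f"staffed_{fn}"]) for fn in SIGNAL_FUNCTIONS)
        kwargs["signal_equipped"] = tuple(
            bool(row[f"equipped_{fn}"]) for fn in SIGNAL_FUNCTIONS)
        if "sector" in df.columns:
            kwargs["sector"] = str(row["sector"])
        if "facility_type" in df.columns:
            kwargs["facility_type"] = str(row["facility_type"])
        for col in ("readiness_score", "level"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = int(row[col])
        out.append(FacilityRecord(**kwargs))
    return out


def write_facilities_geojson(facilities: list[FacilityRecord],
                             path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
            "properties": {"id": f.id, "level": f.level,
                           "readiness_score": f.readiness_score},
        }
        for f in facilities
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


# ---------------------------------------------------------------------------
# Roads: GeoJSON
# ---------------------------------------------------------------------------

def write_roads_geojson(roads: list[RoadSegment], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(seg.start), list(seg.end)]},
            "properties": {"road_class": seg.road_class, "bridge": seg.bridge},
        }
        for seg in roads
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_roads_geojson(path: str | Path) -> list[RoadSegment]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        coords = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        for a, b in zip(coords[:-1], coords[1:]):
            out.append(RoadSegment(start=(a[0], a[1]), end=(b[0], b[1]),
                                   road_class=props.get("road_class",
                                                        "tertiary"),
                                   bridge=bool(props.get("bridge", False))))
    return out


# ---------------------------------------------------------------------------
# Configuration: YAML
# ---------------------------------------------------------------------------

def speeds_to_dict(speeds: SpeedConfig) -> dict:
    return {
        "walking_kmh": {int(k): float(v) for k, v in speeds.walking_kmh.items()},
        "road_kmh": dict(speeds.road_kmh),
        "slope_decay": speeds.slope_decay,
        "attenuate_roads": speeds.attenuate_roads,
        "impassable_classes": sorted(speeds.impassable_classes),
    }


def speeds_from_dict(d: dict) -> SpeedConfig:
    return SpeedConfig(
        walking_kmh={int(k): float(v) for k, v in d["walking_kmh"].items()},
        road_kmh={str(k): float(v) for k, v in d["road_kmh"].items()},
        slope_decay=float(d.get("slope_decay", 3.5)),
        attenuate_roads=bool(d.get("attenuate_roads", False)),
        impassable_classes=frozenset(d.get("impassable_classes", [0])),
    )


def rules_to_dict(rules: CatchmentRule) -> list[dict]:
    return [
        {"level": c.level, "zone": c.zone, "lower_h": c.lower_h,
         "upper_h": c.upper_h, "rank": c.rank}
        for c in rules.classes
    ]


def rules_from_dict(items: list[dict]) -> CatchmentRule:
    return CatchmentRule(tuple(
        CatchmentClass(level=int(d["level"]), zone=str(d["zone"]),
                       lower_h=float(d["lower_h"]), upper_h=float(d["upper_h"]),
                       rank=int(d["rank"]))
        for d in items
    ))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path) -> None:
    """One scenario's access report as a CSV with a band table plus
    weighted journey statistics (minutes and hours)."""
    lines = [f"# model,{report.model}"]
    lines.append(f"# population_total,{report.population_total:.6f}")
    lines.append(f"# population_outside,{report.population_outside:.6f}")
    lines.append("# population_needing_transfer,"
                 f"{report.population_needing_transfer:.6f}")
    for name, stats in (("segment2", report.segment2), ("total", report.total)):
        if stats is None:
            continue
        lines.append(f"# {name}_mean_h,{stats.mean / 60:.6f}")
        lines.append(f"# {name}_sd_h,{stats.sd / 60:.6f}")
        lines.append(f"# {name}_p95_h,{stats.p95 / 60:.6f}")
        lines.append(f"# {name}_max_h,{stats.max / 60:.6f}")
    body = report.band_table.to_csv()
    Path(path).write_text("\n".join(lines) + "\n" + body)
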