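"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text: cells and clinical tables as CSV, tumor-region
masks as GeoJSON (coordinates in µm, same frame as the cells table), derived
thresholds as CSV, and configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import pandas as pd
import yaml
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

#: Channel order of the antibody panel (11 markers).
CHANNELS = [
    "CD57", "NKG2A", "CD16", "HLAE", "CD3", "CD20",
    "CD45", "CD68", "CK", "SMA", "KI67",
]

#: Required columns of the public cells table.
CELL_COLUMNS = ["cell_id", "core_id", "x_um", "y_um"] + CHANNELS

#: The five PCR microsatellite markers, in the conventional order.
MSI_MARKERS = ["bat26", "bat25", "d5s346", "d17s250", "d2s123"]

#: Required columns of the per-patient clinical table.
CLINICAL_COLUMNS = [
    "patient_id", "core_id",
    "os_months", "os_event", "pfs_months", "pfs_event",
    "stage", "ebv_ish",
] + MSI_MARKERS + ["ecad_altered", "p53_positive"]


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CELL_COLUMNS, f"cells table {path}")
    return df


def write_cells(df: pd.DataFrame, path) -> None:
    _require_columns(df, CELL_COLUMNS, "cells table")
    df.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CLINICAL_COLUMNS, f"clinical table {path}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    df.to_csv(path, index=False)


def write_masks(masks: Dict[str, "RegionMask"], path) -> None:
    """Write per-core tumor masks (plus the core boundary) as GeoJSON.

    One feature per tumor region with properties ``core_id`` and
    ``role="tumor"``; one additional feature per core carries the core
    boundary (``role="core"``) so compartment areas round-trip.
    """
    features = []
    for core_id, mask in masks.items():
        geoms = mask.tumor.geoms if isinstance(mask.tumor, MultiPolygon) else [mask.tumor]
        for geom in geoms:
            features.append({
                "type": "Feature",
                "properties": {"core_id": core_id, "role": "tumor"},
                "geometry": mapping(geom),
            })
        features.append({
            "type": "Feature",
            "properties": {"core_id": core_id, "role": "core"},
            "geometry": mapping(mask.core),
        })
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_masks(path) -> Dict[str, "RegionMask"]:
    from .spatial import RegionMask  # deferred to avoid a cycle

    with open(path) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    tumor_parts: Dict[str, list] = {}
    cores: Dict[str, Polygon] = {}
    for feat in collection.get("features", []):
        props = feat.get("properties") or {}
        core_id = props.get("core_id")
        if core_id is None:
            raise SchemaError(f"{path}: feature without a core_id property")
        geom = shape(feat["geometry"])
        if props.get("role") == "core":
            cores[core_id] = geom
        else:
            tumor_parts.setdefault(core_id, []).append(geom)
    masks = {}
    for core_id, parts in tumor_parts.items():
        polys = []
        for g in parts:
            polys.extend(g.geoms if isinstance(g, MultiPolygon) else [g])
        tumor = MultiPolygon(polys) if len(polys) > 1 else polys[0]
        core = cores.get(core_id)
        if core is None:
            # No explicit boundary: fall back to the tumor envelope.
            core = tumor.convex_hull
        masks[core_id] = RegionMask(core_id=core_id, tumor=tumor, core=core)
    return masks


def write_thresholds(panel, path) -> None:
    rows = [
        {"channel": ch, "threshold": panel.thresholds[ch],
         "method": panel.methods.get(ch, "distribution")}
        for ch in panel.channels if ch in panel.thresholds
    ]
    pd.DataFrame(rows, columns=["channel", "threshold", "method"]).to_csv(path, index=False)


def read_thresholds(path):
    from .phenotyping import MarkerPanel

    df = pd.read_csv(path)
    _require_columns(df, ["channel", "threshold", "method"], f"thresholds table {path}")
    return MarkerPanel(
        channels=list(df["channel"]),
        thresholds=dict(zip(df["channel"], df["threshold"])),
        methods=dict(zip(df["channel"], df["method"])),
    )


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
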