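"""Readers and writers for the pipeline's file artefacts.

Observation tables are CSV (site, year, species, x_m, y_m, count);
landscapes travel either as GeoJSON polygon collections with a
``habitat`` property per field, or as a whitespace text raster of integer
codes plus a JSON sidecar mapping codes to habitat classes.  All readers
validate and report offending rows / features by number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import HABITAT_CLASSES, Landscape, N_HABITATS, OBS_COLUMNS, SPECIES


class ValidationError(ValueError):
    """Malformed input file; message carries the row/feature number."""


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["species"] not in SPECIES:
            raise ValidationError(
                f"{path}:{line}: unknown species {row['species']!r}"
            )
        try:
            count = int(row["count"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path}:{line}: count is not an integer") from None
        if count < 1:
            raise ValidationError(f"{path}:{line}: count must be >= 1, got {count}")
        if not (np.isfinite(row["x_m"]) and np.isfinite(row["y_m"])):
            raise ValidationError(f"{path}:{line}: non-finite coordinates")
    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    return df[OBS_COLUMNS]


def write_observations(df: pd.DataFrame, path) -> None:
    df[OBS_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


def write_landscape_geojson(land: Landscape, path) -> None:
    features = []
    fs = land.field_size_m
    for j in range(land.ny):
        for i in range(land.nx):
            x0, y0 = i * fs, j * fs
            x1, y1 = min(x0 + fs, land.width_m), min(y0 + fs, land.height_m)
            ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"habitat": HABITAT_CLASSES[land.labels[j, i]]},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "field_size_m": land.field_size_m,
            "width_m": land.width_m,
            "height_m": land.height_m,
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_landscape_geojson(path) -> Landscape:
    with open(path) as fh:
        doc = json.load(fh)
    props = doc.get("properties", {})
    try:
        fs = float(props["field_size_m"])
        width = float(props["width_m"])
        height = float(props["height_m"])
    except KeyError as e:
        raise ValidationError(f"{path}: missing collection property {e}") from None
    nx = max(1, int(np.ceil(width / fs)))
    ny = max(1, int(np.ceil(height / fs)))
    labels = np.full((ny, nx), -1, dtype=np.int8)
    for k, feat in enumerate(doc.get("features", [])):
        habitat = (feat.get("properties") or {}).get("habitat")
        if habitat is None:
            raise ValidationError(f"{path}: feature {k} lacks a 'habitat' property")
        if habitat not in HABITAT_CLASSES:
            raise ValidationError(
                f"{path}: feature {k} has unknown habitat {habitat!r}"
            )
        coords = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        cx, cy = coords[:-1, 0].mean(), coords[:-1, 1].mean()
        i, j = int(cx // fs), int(cy // fs)
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValidationError(f"{path}: feature {k} lies outside the extent")
        labels[j, i] = HABITAT_CLASSES.index(habitat)
    if (labels < 0).any():
        raise ValidationError(f"{path}: landscape grid has unlabelled fields")
    return Landscape(labels=labels, field_size_m=fs, width_m=width, height_m=height)


def write_landscape_raster(land: Landscape, txt_path, sidecar_path) -> None:
    np.savetxt(txt_path, land.labels, fmt="%d")
    sidecar = {
        "codes": {str(i): h for i, h in enumerate(HABITAT_CLASSES)},
        "cell_size_m": land.field_size_m,
        "width_m": land.width_m,
        "height_m": land.height_m,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_landscape_raster(txt_path, sidecar_path) -> Landscape:
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    codes = {int(k): v for k, v in sidecar["codes"].items()}
    for code, name in codes.items():
        if not (0 <= code < N_HABITATS) or HABITAT_CLASSES[code] != name:
            raise ValidationError(
                f"{sidecar_path}: code {code} -> {name!r} does not match the "
                "canonical habitat coding"
            )
    labels = np.loadtxt(txt_path, dtype=int, ndmin=2)
    if labels.min() < 0 or labels.max() >= N_HABITATS:
        raise ValidationError(f"{txt_path}: raster codes outside [0, {N_HABITATS})")
    return Landscape(
        labels=labels.astype(np.int8),
        field_size_m=float(sidecar["cell_size_m"]),
        width_m=float(sidecar["width_m"]),
        height_m=float(sidecar["height_m"]),
    )


def read_landscape(path) -> Landscape:
    """Dispatch on extension: .geojson/.json -> polygons, .txt -> raster
    (expects a ``<stem>.meta.json`` sidecar)."""
    p = Path(path)
    if p.suffix in (".geojson", ".json"):
        return read_landscape_geojson(p)
    if p.suffix == ".txt":
        return read_landscape_raster(p, p.with_suffix(".meta.json"))
    raise ValidationError(f"unrecognized landscape format: {p.name}")


def write_mcps_geojson(mcps: dict, path) -> None:
    features = []
    for (site, year), mcp in sorted(mcps.items()):
        ring = [[float(x), float(y)] for x, y in mcp.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"site": site, "year": int(year), "area_km2": mcp.area_km2},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
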