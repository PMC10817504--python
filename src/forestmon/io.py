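"""Readers and writers for the pipeline's file formats.

Rasters are multiband TIFFs with the grid geometry, band names, and
nodata convention embedded as a JSON document in the TIFF
ImageDescription tag; float rasters round-trip at float32 precision,
integer rasters bit-exactly.  Vectors are GeoJSON FeatureCollections
(compartments carry ``id``, ``species_code``, ``area_ha``; training
points carry ``class_code``).  Tables are plain CSV.  Run configuration
is YAML.

A single coordinate frame per run is assumed: the ``crs_label`` of the
grid is carried verbatim and compared on read, never reprojected.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .collection import Scene
from .damage import DamageReport
from .errors import FormatError
from .grid import GridSpec
from .simulate import Compartment, CompartmentSet
from .species import TrainingPoint

_META_KEY = "forestmon"
#: Sentinel-2 L2A surface reflectance is distributed as int * 1/10000.
L2A_SCALE = 10000.0


@dataclass
class RasterMeta:
    grid: GridSpec
    band_names: list[str]
    nodata: float | int | None = None
    extra: dict | None = None


# ----------------------------------------------------------------------
# rasters


def write_raster(
    path: str | Path,
    data: np.ndarray,
    grid: GridSpec,
    band_names: Sequence[str],
    nodata: float | int | None = None,
    extra: dict | None = None,
) -> None:
    """Write a (bands, H, W) or (H, W) array as a described multiband TIFF."""
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"raster array must be 2-D or 3-D, got shape {arr.shape}")
    if arr.shape[0] != len(band_names):
        raise FormatError(f"{arr.shape[0]} bands but {len(band_names)} band names")
    if arr.shape[1:] != grid.shape:
        raise FormatError(f"raster shape {arr.shape[1:]} does not match grid {grid.shape}")
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    desc = json.dumps(
        {
            _META_KEY: {
                "grid": grid.to_dict(),
                "band_names": list(band_names),
                "nodata": nodata,
                "extra": extra or {},
            }
        }
    )
    tifffile.imwrite(Path(path), arr, description=desc, photometric="minisblack")


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterMeta]:
    """Read a raster written by :func:`write_raster`; returns (bands, H, W)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)[_META_KEY]
    except (json.JSONDecodeError, KeyError, TypeError):
        raise FormatError(f"{path}: missing or malformed grid metadata (ImageDescription)") from None
    try:
        grid = GridSpec.from_dict(meta["grid"])
        band_names = list(meta["band_names"])
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: metadata lacks field {e}") from None
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(band_names):
        raise FormatError(f"{path}: {arr.shape[0]} bands but {len(band_names)} names in metadata")
    return arr, RasterMeta(grid, band_names, meta.get("nodata"), meta.get("extra") or {})


def write_scene(path: str | Path, scene: Scene, scale_l2a: bool = False) -> None:
    """Write a scene as one multiband TIFF: reflectance bands then the QA band.

    With ``scale_l2a`` reflectance is exported in the L2A integer
    convention (x 10000, uint16); otherwise as float32 in [0, 1].
    """
    names = scene.band_names + ["QA"]
    if scale_l2a:
        bands = [np.round(scene.bands[b] * L2A_SCALE).astype(np.uint16) for b in scene.band_names]
        stack = np.stack(bands + [scene.qa.astype(np.uint16)])
    else:
        stack = np.stack(
            [scene.bands[b].astype(np.float32) for b in scene.band_names]
            + [scene.qa.astype(np.float32)]
        )
    desc_extra = {
        "acquisition_date": scene.date.isoformat(),
        "cloudy_pixel_percentage": scene.cloudy_pixel_percentage,
        "l2a_scaled": scale_l2a,
    }
    write_raster(path, stack, scene.grid, names, nodata=None, extra=desc_extra)


def read_scene(path: str | Path) -> Scene:
    arr, meta = read_raster(path)
    extra = meta.extra or {}
    for key in ("acquisition_date", "cloudy_pixel_percentage"):
        if key not in extra:
            raise FormatError(f"{path}: scene metadata lacks {key!r}")
    qa_idx = [i for i, n in enumerate(meta.band_names) if n.upper() in ("QA", "QA60", "QA10")]
    if not qa_idx:
        raise FormatError(f"{path}: no QA band among {meta.band_names}")
    qi = qa_idx[0]
    bands = {}
    for i, n in enumerate(meta.band_names):
        if i == qi:
            continue
        b = arr[i].astype(np.float64)
        if extra.get("l2a_scaled"):
            b = b / L2A_SCALE
        bands[n] = b
    return Scene(
        bands=bands,
        qa=arr[qi].astype(np.uint16),
        date=dt.date.fromisoformat(extra["acquisition_date"]),
        cloudy_pixel_percentage=float(extra["cloudy_pixel_percentage"]),
        grid=meta.grid,
    )


# ----------------------------------------------------------------------
# vectors


def write_compartments(path: str | Path, compartments: CompartmentSet, crs_label: str = "local-metric") -> None:
    features = [
        {
            "type": "Feature",
            "id": c.compartment_id,
            "geometry": mapping(c.polygon),
            "properties": {
                "id": c.compartment_id,
                "species_code": c.species_code,
                "area_ha": c.area_ha,
            },
        }
        for c in compartments
    ]
    doc = {"type": "FeatureCollection", "crs_label": crs_label, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_compartments(path: str | Path) -> CompartmentSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
        features = doc["features"]
    except (json.JSONDecodeError, KeyError) as e:
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection ({e})") from None
    comps = []
    for f in features:
        props = f.get("properties") or {}
        fid = props.get("id", f.get("id"))
        for field in ("species_code", "area_ha"):
            if field not in props:
                raise FormatError(f"{path}: feature {fid!r} lacks property {field!r}")
        comps.append(
            Compartment(
                compartment_id=str(fid),
                polygon=shape(f["geometry"]),
                species_code=int(props["species_code"]),
                area_ha=float(props["area_ha"]),
            )
        )
    return CompartmentSet(comps)


def write_points(path: str | Path, points: list[TrainingPoint]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": {"class_code": p.class_code},
        }
        for p in points
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_points(path: str | Path) -> list[TrainingPoint]:
    path = Path(path)
    doc = json.loads(path.read_text())
    points = []
    for i, f in enumerate(doc.get("features", [])):
        props = f.get("properties") or {}
        if "class_code" not in props:
            raise FormatError(f"{path}: feature {i} lacks property 'class_code'")
        x, y = f["geometry"]["coordinates"][:2]
        points.append(TrainingPoint(float(x), float(y), int(props["class_code"])))
    return points


# ----------------------------------------------------------------------
# tables

REPORT_COLUMNS = [
    "compartment_id",
    "year",
    "damage_type",
    "damaged_area_ha",
    "total_area_ha",
    "damage_ratio_pct",
]


def write_reports(path: str | Path, reports: list[DamageReport]) -> None:
    rows = [
        {
            "compartment_id": r.compartment_id,
            "year": r.year,
            "damage_type": r.damage_type,
            "damaged_area_ha": r.damaged_area_ha,
            "total_area_ha": r.total_area_ha,
            "damage_ratio_pct": r.ratio_pct,
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_reports(path: str | Path) -> list[DamageReport]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: report CSV lacks columns {missing}")
    reports = []
    for i, row in df.iterrows():
        if row["damaged_area_ha"] > row["total_area_ha"]:
            raise FormatError(
                f"{path} row {i}: damaged_area_ha > total_area_ha — the damage "
                "ratio (damaged/total * 100) is only defined on [0, 100]%"
            )
        reports.append(
            DamageReport(
                compartment_id=str(row["compartment_id"]),
                year=int(row["year"]),
                damage_type=str(row["damage_type"]),
                damaged_area_ha=float(row["damaged_area_ha"]),
                total_area_ha=float(row["total_area_ha"]),
            )
        )
    return reports


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# config / dates


def parse_date(text: str) -> dt.date:
    """Accept ISO-8601 ('2017-04-14') and field-report style ('14 April 2017')."""
    text = str(text).strip()
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        pass
    for fmt in ("%d %B %Y", "%d %b %Y"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise FormatError(f"unrecognised date {text!r}; use ISO-8601 or e.g. '14 April 2017'")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: configuration must be a YAML mapping")
    return doc
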