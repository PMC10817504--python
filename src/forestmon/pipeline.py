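"""End-to-end run: filter -> composite -> NDVI -> anomaly -> damage
validation, plus species classification and the ROI-median time series.

Inputs are either a synthetic-archive configuration (:class:`SimConfig`)
or directories of real scene TIFFs with compartment GeoJSON and report
CSV files.  Every run writes its artifacts under one output directory
together with a machine-readable manifest (config hash, seed, package
versions) sufficient to reproduce it; inputs are never modified.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .collection import (
    SceneCollection,
    filter_bounds,
    filter_cloud_metadata,
    filter_date,
    make_rgb,
    mask_collection,
    reduce,
)
from .damage import (
    AccuracyEntry,
    accuracies,
    classify_damage,
    confusion,
    mean_accuracies,
    reference_damage_map,
    round_pct,
)
from .errors import FormatError
from .indices import IndexRaster, median_timeseries, multi_year_stats, ndvi, normality_check, zndvi
from .io import (
    read_compartments,
    read_reports,
    read_scene,
    write_compartments,
    write_raster,
    write_reports,
    write_table,
)
from .simulate import SimConfig, make_collection, make_compartments, make_reports
from .species import (
    auto_training_points,
    classify_species,
    sample_training,
    species_accuracy,
    train_rf,
    zonal_majority,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: Path
    seed: int = 7
    sim: SimConfig | None = None
    scene_dir: Path | None = None
    compartments_path: Path | None = None
    reports_path: Path | None = None
    # vegetation window applied to every year, as (month, day) pairs; the
    # date filter itself is half-open [start, end)
    season_start: tuple[int, int] = (4, 14)
    season_end: tuple[int, int] = (10, 15)
    max_cloud_pct: float = 5.0
    z_threshold: float = -0.5
    ratio_threshold: float = 30.0
    rf_trees: int = 100
    rf_vars_per_split: int = 10
    species_year: int | None = None
    normality_points: int = 100

    def validate(self) -> None:
        if (self.sim is None) == (self.scene_dir is None):
            raise ValueError("exactly one of `sim` and `scene_dir` must be given")
        if self.scene_dir is not None:
            for name in ("scene_dir", "compartments_path", "reports_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} {p} does not exist")
        s, e = self.season_start, self.season_end
        if s >= e:
            raise ValueError(
                f"season end (month,day)={e} is not after season start {s}: "
                "the date window [start, end) would be empty"
            )
        if not 0 <= self.max_cloud_pct <= 100:
            raise ValueError("max_cloud_pct must lie in [0, 100]")


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_scene_collections(cfg: RunConfig) -> dict[int, SceneCollection]:
    scenes = sorted(Path(cfg.scene_dir).glob("*.tif")) + sorted(Path(cfg.scene_dir).glob("*.tiff"))
    if not scenes:
        raise FormatError(f"no .tif scene found under {cfg.scene_dir}")
    by_year: dict[int, list] = {}
    for p in scenes:
        s = read_scene(p)
        by_year.setdefault(s.date.year, []).append(s)
    return {
        y: SceneCollection(sorted(ss, key=lambda s: s.date))
        for y, ss in sorted(by_year.items())
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and write all artifacts under cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        sim = cfg.sim
        compartments = make_compartments(sim)
        reports = make_reports(sim)
        collections = {y: make_collection(sim, y) for y in sim.years}
        write_compartments(out / "compartments.geojson", compartments, sim.grid.crs_label)
        write_reports(out / "reports.csv", reports)
    else:
        compartments = read_compartments(cfg.compartments_path)
        reports = read_reports(cfg.reports_path)
        collections = _load_scene_collections(cfg)

    years = sorted(collections)
    roi = shapely.union_all([c.polygon for c in compartments])
    grid = collections[years[0]].grid

    # --- per-year filtering, masking, compositing, NDVI ---------------
    annual_ndvi: dict[int, IndexRaster] = {}
    masked: dict[int, SceneCollection] = {}
    for y in years:
        coll = collections[y]
        coll = filter_bounds(coll, roi)
        coll = filter_date(coll, dt.date(y, *cfg.season_start), dt.date(y, *cfg.season_end))
        coll = filter_cloud_metadata(coll, cfg.max_cloud_pct)
        coll = mask_collection(coll)
        masked[y] = coll
        comp = reduce(coll, "median")
        annual_ndvi[y] = ndvi(comp, label=str(y))
        write_raster(
            out / f"composite_{y}.tif",
            np.stack([comp.bands[b] for b in comp.band_names]),
            grid,
            comp.band_names,
            nodata=float("nan"),
        )
        write_raster(out / f"rgb_{y}.tif", make_rgb(comp), grid, ["R", "G", "B", "A"])
        write_raster(out / f"ndvi_{y}.tif", annual_ndvi[y].values, grid, ["ndvi"], nodata=float("nan"))
        log.info("year %d: %d scenes after filtering", y, len(coll))

    # --- anomalies, damage maps, validation ---------------------------
    mean_r, std_r = multi_year_stats([annual_ndvi[y] for y in years])
    write_raster(out / "ndvi_mean.tif", mean_r.values, grid, ["ndvi_mean"], nodata=float("nan"))
    write_raster(out / "ndvi_std.tif", std_r.values, grid, ["ndvi_std"], nodata=float("nan"))

    confusion_rows, acc_entries, norm_rows = [], [], []
    zmaps = {}
    for y in years:
        z = zndvi(annual_ndvi[y], mean_r, std_r)
        zmaps[y] = z
        write_raster(out / f"zndvi_{y}.tif", z.values, grid, ["zndvi"], nodata=float("nan"))
        classified = classify_damage(z, cfg.z_threshold)
        reference = reference_damage_map(compartments, reports, y, grid, cfg.ratio_threshold)
        write_raster(out / f"damage_classified_{y}.tif", classified.values, grid, ["damage"], nodata=-1)
        write_raster(out / f"damage_reference_{y}.tif", reference.values, grid, ["damage"], nodata=-1)
        m = confusion(classified, reference)
        confusion_rows.append(
            {"year": y, "n11": m.n11, "n10": m.n10, "n01": m.n01, "n00": m.n00, "total": m.total}
        )
        if not m.empty:
            acc_entries.append(accuracies(m))
        try:
            w, p = normality_check(z, n=cfg.normality_points, seed=cfg.seed + y)
            norm_rows.append({"year": y, "shapiro_w": w, "p_value": p, "n": cfg.normality_points})
        except Exception as e:  # per-year failure isolated
            log.warning("normality check failed for %d: %s", y, e)
            norm_rows.append({"year": y, "shapiro_w": float("nan"), "p_value": float("nan"), "n": 0})

    write_table(out / "confusion.csv", pd.DataFrame(confusion_rows))
    acc_rows = [
        {
            "year": e.year,
            "producer_pct": round_pct(e.producer_pct),
            "user_pct": round_pct(e.user_pct),
            "total_pct": round_pct(e.total_pct),
        }
        for e in acc_entries
    ]
    mean_entry = mean_accuracies(acc_entries) if acc_entries else None
    if mean_entry:
        acc_rows.append(
            {
                "year": "mean",
                "producer_pct": round_pct(mean_entry.producer_pct),
                "user_pct": round_pct(mean_entry.user_pct),
                "total_pct": round_pct(mean_entry.total_pct),
            }
        )
    write_table(out / "accuracy.csv", pd.DataFrame(acc_rows))
    write_table(out / "normality.csv", pd.DataFrame(norm_rows))

    # --- ROI-median NDVI time series ----------------------------------
    all_scenes = [s for y in years for s in masked[y]]
    series = median_timeseries(
        SceneCollection(all_scenes, grid=grid, band_names=masked[years[0]].band_names), roi
    )
    write_table(out / "timeseries.csv", series)

    # --- species classification ---------------------------------------
    sp_year = cfg.species_year if cfg.species_year is not None else years[-1]
    sp_comp = reduce(masked[sp_year], "median")
    points = auto_training_points(compartments, grid, seed=cfg.seed + 1)
    ts = sample_training(points, sp_comp)
    model = train_rf(ts, cfg.rf_trees, cfg.rf_vars_per_split, seed=cfg.seed + 2)
    sp_map = classify_species(model, sp_comp)
    write_raster(out / "species_map.tif", sp_map.values, grid, ["species_code"], nodata=-1,
                 extra={"legend": sp_map.legend})
    table = zonal_majority(sp_map, compartments)
    write_table(out / "species_compartments.csv", table)
    sp_acc_all = species_accuracy(table)
    sp_acc_forest = species_accuracy(table, exclude_clearcut=True)
    write_table(
        out / "species_accuracy.csv",
        pd.DataFrame(
            [
                {"subset": "all", "accuracy_pct": round_pct(sp_acc_all)},
                {"subset": "excluding_clearcut", "accuracy_pct": round_pct(sp_acc_forest)},
            ]
        ),
    )

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "forestmon": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "years": years,
        "species_year": sp_year,
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "out_dir": out,
        "years": years,
        "compartments": compartments,
        "reports": reports,
        "annual_ndvi": annual_ndvi,
        "zndvi": zmaps,
        "confusion": confusion_rows,
        "accuracy": acc_entries,
        "mean_accuracy": mean_entry,
        "normality": norm_rows,
        "timeseries": series,
        "species_table": table,
        "species_accuracy_pct": sp_acc_all,
        "species_accuracy_forest_pct": sp_acc_forest,
    }
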