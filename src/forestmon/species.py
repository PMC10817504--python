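"""Dominant tree-species classification and compartment-level validation.

A random forest (100 trees, up to 10 candidate variables per split) is
trained on band values sampled from a composite at manually or
automatically selected points, applied per pixel, then aggregated to the
compartment level by zonal majority (the modal class over each
compartment's pixels).  Agreement with the field species attribute gives
the compartment-level total accuracy

    accuracy = correctly classified compartments / total compartments * 100,

optionally restricted to forest-covered compartments (clearcuts excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .collection import Composite
from .errors import FormatError, SamplingError, TrainingError
from .grid import GridSpec
from .simulate import CLEARCUT_CODE, SPECIES_LEGEND, TRAINING_COUNTS, CompartmentSet

log = logging.getLogger(__name__)

NODATA = -1


@dataclass
class TrainingPoint:
    x: float
    y: float
    class_code: int


@dataclass
class TrainingSet:
    """Feature matrix + labels extracted from a composite at point locations."""

    features: np.ndarray  # (n, n_features)
    labels: np.ndarray  # (n,)
    feature_names: list[str]
    points: list[TrainingPoint]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        if len(self.labels) and len(np.unique(self.labels)) < 1:
            raise ValueError("training set must represent at least one class")

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}


@dataclass
class SpeciesMap:
    """Per-pixel predicted class codes; -1 is nodata."""

    values: np.ndarray
    legend: dict[int, str]
    grid: GridSpec


@dataclass
class SpeciesModel:
    """A fitted random forest plus the feature (band) order it expects."""

    forest: RandomForestClassifier
    feature_names: list[str]

    @property
    def oob_accuracy(self) -> float | None:
        return getattr(self.forest, "oob_score_", None)


def auto_training_points(
    compartments: CompartmentSet,
    grid: GridSpec,
    class_counts: dict[int, int] | None = None,
    seed: int | None = None,
) -> list[TrainingPoint]:
    """Sample training points from ground-truth compartments.

    Mirrors the field protocol's per-class point counts (default 15 black
    locust, 27 Scots pine, 40 pedunculate oak, 22 red oak, 19 clearcut);
    points are pixel centres drawn without replacement within each class.
    """
    counts = dict(TRAINING_COUNTS if class_counts is None else class_counts)
    rng = np.random.default_rng(seed)
    species = compartments.species_raster(grid)
    points: list[TrainingPoint] = []
    for code in sorted(counts):
        rows, cols = np.nonzero(species == code)
        if len(rows) < counts[code]:
            raise SamplingError(
                f"class {SPECIES_LEGEND.get(code, code)} has {len(rows)} pixels, "
                f"cannot draw {counts[code]} training points"
            )
        sel = rng.choice(len(rows), size=counts[code], replace=False)
        for i in sel:
            x, y = grid.pixel_centre(int(rows[i]), int(cols[i]))
            points.append(TrainingPoint(x, y, code))
    return points


def sample_training(points: list[TrainingPoint], comp: Composite) -> TrainingSet:
    """Extract feature vectors (all composite bands) at each point's pixel.

    Points outside the grid or on nodata pixels are dropped with a warning.
    """
    names = comp.band_names
    feats, labels, kept = [], [], []
    for p in points:
        loc = comp.grid.point_to_pixel(p.x, p.y)
        if loc is None:
            log.warning("training point (%.1f, %.1f) outside grid; dropped", p.x, p.y)
            continue
        vec = np.array([comp.bands[b][loc] for b in names])
        if not np.all(np.isfinite(vec)):
            log.warning("training point (%.1f, %.1f) on nodata pixel; dropped", p.x, p.y)
            continue
        feats.append(vec)
        labels.append(p.class_code)
        kept.append(p)
    if not feats:
        raise SamplingError("no training point fell on a valid pixel")
    return TrainingSet(np.array(feats), np.array(labels, dtype=np.int64), list(names), kept)


def train_rf(
    ts: TrainingSet,
    n_trees: int = 100,
    vars_per_split: int = 10,
    seed: int | None = None,
    oob: bool = False,
) -> SpeciesModel:
    """Fit the seeded random forest (100 trees / 10 variables per split by
    default; the split-variable count is clamped to the feature count)."""
    if len(np.unique(ts.labels)) < 2:
        raise TrainingError("training set holds a single class; nothing to separate")
    n_features = ts.features.shape[1]
    mf = vars_per_split
    if mf > n_features:
        log.warning(
            "vars_per_split=%d exceeds the %d available features; clamped", mf, n_features
        )
        mf = n_features
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mf,
        random_state=seed,
        oob_score=oob,
        n_jobs=1,
    )
    forest.fit(ts.features, ts.labels)
    return SpeciesModel(forest, list(ts.feature_names))


def classify_species(model: SpeciesModel, comp: Composite) -> SpeciesMap:
    """Per-pixel prediction over the composite; nodata propagates."""
    if list(comp.band_names) != model.feature_names:
        raise FormatError(
            f"composite bands {comp.band_names} do not match the model's "
            f"training features {model.feature_names}"
        )
    stack = np.stack([comp.bands[b] for b in model.feature_names], axis=-1)
    valid = np.all(np.isfinite(stack), axis=-1)
    out = np.full(comp.grid.shape, NODATA, dtype=np.int16)
    if valid.any():
        out[valid] = model.forest.predict(stack[valid]).astype(np.int16)
    return SpeciesMap(out, dict(SPECIES_LEGEND), comp.grid)


def zonal_majority(sm: SpeciesMap, compartments: CompartmentSet) -> pd.DataFrame:
    """Modal predicted class per compartment, against the field attribute.

    Ties break to the lowest class code (flagged); compartments with zero
    valid pixels get majority_code -1 and are excluded from the accuracy.
    Columns: compartment_id, field_code, majority_code, n_pixels, tie,
    agreement.
    """
    labels = compartments.label_raster(sm.grid)
    rows = []
    for i, c in enumerate(compartments):
        vals = sm.values[(labels == i) & (sm.values != NODATA)]
        if vals.size == 0:
            log.warning("compartment %s has no classified pixel; excluded", c.compartment_id)
            rows.append((c.compartment_id, c.species_code, NODATA, 0, False, False))
            continue
        counts = np.bincount(vals)
        top = int(np.argmax(counts))  # argmax returns the lowest code on ties
        tie = int((counts == counts[top]).sum()) > 1
        if tie:
            log.info("compartment %s: majority tie, resolved to class %d", c.compartment_id, top)
        rows.append(
            (c.compartment_id, c.species_code, top, int(vals.size), tie, top == c.species_code)
        )
    return pd.DataFrame(
        rows,
        columns=["compartment_id", "field_code", "majority_code", "n_pixels", "tie", "agreement"],
    )


def species_accuracy(
    table: pd.DataFrame, exclude_clearcut: bool = False, clearcut_code: int = CLEARCUT_CODE
) -> float:
    """Compartment-agreement accuracy in percent.

    Counts compartments with a valid majority (ties included, resolved by
    the lowest-code rule); optionally restricted to compartments whose
    field class is not clearcut.
    """
    if table.empty:
        raise ValueError("empty compartment table")
    t = table[table["majority_code"] != NODATA]
    if exclude_clearcut:
        t = t[t["field_code"] != clearcut_code]
    if t.empty:
        raise ValueError("no comparable compartment after filtering")
    return 100.0 * float(t["agreement"].sum()) / len(t)


def agreement_accuracy(n_agree: int, n_total: int) -> float:
    """Compartment-agreement accuracy from plain counts."""
    if n_total <= 0:
        raise ValueError("total compartment count must be positive")
    if not 0 <= n_agree <= n_total:
        raise ValueError("agreements must lie in [0, total]")
    return 100.0 * n_agree / n_total
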