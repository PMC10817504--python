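"""Damage classification and confusion-matrix validation.

Field damage reports are given per forest compartment; the damage ratio

    ratio = damaged area / total area * 100          (percent)

reclassifies a compartment to reference damage (1) when the ratio reaches
30%, no damage (0) otherwise.  The satellite side classifies a pixel as
damage when its standardized NDVI anomaly falls strictly below -0.5.
Both maps use 1 = damage internally; the field convention that codes
damage as 0 on the anomaly raster is available as an export flag.

Accuracy follows the standard remote-sensing confusion-matrix measures:
producer's accuracy PA = n11 / (n11 + n01) (reference-damage pixels
found), user's accuracy UA = n11 / (n11 + n10) (classified-damage pixels
that are real), total accuracy TA = (n11 + n00) / total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .errors import DanglingReferenceError, GridMismatchError
from .grid import GridSpec
from .indices import IndexRaster

log = logging.getLogger(__name__)

NODATA = -1  # in int8 binary maps

#: Default reclassification threshold on the compartment damage ratio (%).
RATIO_THRESHOLD = 30.0
#: Default anomaly threshold: a pixel is damage when z < this value.
Z_THRESHOLD = -0.5


def round_pct(x: float | None, ndigits: int = 2) -> float | None:
    """Round a percentage for reporting, half away from zero at ties.

    Matches how the field tables are printed (e.g. a mean of 99.625
    appears as 99.63).
    """
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DamageReport:
    """One compartment-year row of a field damage report."""

    compartment_id: str
    year: int
    damage_type: str
    damaged_area_ha: float
    total_area_ha: float
    frequency_pct: float = 0.0
    intensity_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.total_area_ha <= 0:
            raise ValueError("total_area_ha must be positive")
        if not 0 <= self.damaged_area_ha <= self.total_area_ha:
            raise ValueError(
                "damaged_area_ha must lie in [0, total_area_ha] "
                "(the damage ratio is a fraction of the compartment)"
            )
        for name in ("frequency_pct", "intensity_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")

    @property
    def ratio_pct(self) -> float:
        return damage_ratio(self.damaged_area_ha, self.total_area_ha)


def damage_ratio(damaged_area_ha: float, total_area_ha: float) -> float:
    """Damaged share of a compartment, percent of its total area."""
    if total_area_ha <= 0:
        raise ValueError("total_area_ha must be positive")
    return damaged_area_ha / total_area_ha * 100.0


@dataclass
class BinaryDamageMap:
    """2-D {1 = damage, 0 = no damage, -1 = nodata} grid."""

    values: np.ndarray
    source: str  # "classified" | "reference"
    year: int
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("damage map shape does not match grid")
        bad = ~np.isin(self.values, (NODATA, 0, 1))
        if bad.any():
            raise ValueError("damage map values must be in {1, 0, nodata}")

    @property
    def valid(self) -> np.ndarray:
        return self.values != NODATA


def to_field_coding(m: BinaryDamageMap) -> np.ndarray:
    """Export with the field-report raster convention (0 = damage, 1 = none)."""
    out = m.values.copy()
    ok = out != NODATA
    out[ok] = 1 - out[ok]
    return out


def from_field_coding(values: np.ndarray, source: str, year: int, grid: GridSpec) -> BinaryDamageMap:
    flipped = values.copy()
    ok = flipped != NODATA
    flipped[ok] = 1 - flipped[ok]
    return BinaryDamageMap(flipped, source, year, grid)


def reference_damage_map(
    compartments: "CompartmentSet",
    reports: Iterable[DamageReport],
    year: int,
    grid: GridSpec,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> BinaryDamageMap:
    """Rasterize compartment damage reports to a reference damage map.

    Each compartment's pixels (centre containment) get 1 when the
    compartment's damage ratio for the year reaches ``ratio_threshold``
    (ties count as damage), else 0.  Compartments with no report for the
    year are no-damage; pixels outside every compartment are nodata.
    Multiple same-year reports for one compartment are summed by area.
    """
    ids = {c.compartment_id for c in compartments}
    damaged: dict[str, float] = {}
    total: dict[str, float] = {}
    for r in reports:
        if r.compartment_id not in ids:
            raise DanglingReferenceError(
                f"report references unknown compartment {r.compartment_id!r}"
            )
        if r.year != year:
            continue
        damaged[r.compartment_id] = damaged.get(r.compartment_id, 0.0) + r.damaged_area_ha
        total[r.compartment_id] = r.total_area_ha

    labels = compartments.label_raster(grid)
    out = np.full(grid.shape, NODATA, dtype=np.int8)
    for i, c in enumerate(compartments):
        ratio = 0.0
        if c.compartment_id in damaged:
            ratio = damage_ratio(damaged[c.compartment_id], total[c.compartment_id])
        out[labels == i] = 1 if ratio >= ratio_threshold else 0
    return BinaryDamageMap(out, "reference", year, grid)


def classify_damage(z: IndexRaster, threshold: float = Z_THRESHOLD) -> BinaryDamageMap:
    """Threshold an anomaly raster: z strictly below the threshold is damage."""
    v = z.values
    out = np.full(z.grid.shape, NODATA, dtype=np.int8)
    finite = np.isfinite(v)
    out[finite & (v < threshold)] = 1
    out[finite & (v >= threshold)] = 0
    year = int(z.label) if str(z.label).isdigit() else 0
    return BinaryDamageMap(out, "classified", year, z.grid)


@dataclass
class ConfusionMatrix:
    """2x2 damage counts; rows = classified, columns = reference."""

    n11: int
    n10: int
    n01: int
    n00: int
    year: int = 0
    empty: bool = field(default=False)

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def confusion(classified: BinaryDamageMap, reference: BinaryDamageMap) -> ConfusionMatrix:
    """Counts over pixels valid in both maps."""
    if classified.grid != reference.grid:
        raise GridMismatchError("classified and reference maps are not on one grid")
    if classified.year != reference.year:
        raise ValueError(
            f"year mismatch: classified {classified.year} vs reference {reference.year}"
        )
    ok = classified.valid & reference.valid
    c, r = classified.values[ok], reference.values[ok]
    m = ConfusionMatrix(
        n11=int(((c == 1) & (r == 1)).sum()),
        n10=int(((c == 1) & (r == 0)).sum()),
        n01=int(((c == 0) & (r == 1)).sum()),
        n00=int(((c == 0) & (r == 0)).sum()),
        year=classified.year,
    )
    if m.total == 0:
        m.empty = True
        log.warning("confusion matrix for %s is empty: no co-valid pixels", classified.year)
    return m


@dataclass
class AccuracyEntry:
    """Producer's / user's / total accuracy for one year, in percent.

    ``None`` marks a not-applicable ratio (empty denominator), which is
    distinct from an accuracy of 0.
    """

    year: int
    producer_pct: float | None
    user_pct: float | None
    total_pct: float | None


def accuracies(m: ConfusionMatrix) -> AccuracyEntry:
    if m.total == 0:
        raise ValueError("cannot compute accuracies of an empty confusion matrix")
    ref_damage = m.n11 + m.n01
    cls_damage = m.n11 + m.n10
    pa = 100.0 * m.n11 / ref_damage if ref_damage else None
    ua = 100.0 * m.n11 / cls_damage if cls_damage else None
    ta = 100.0 * (m.n11 + m.n00) / m.total
    if pa is None:
        log.warning("year %s: no reference damage; producer's accuracy not applicable", m.year)
    if ua is None:
        log.warning("year %s: no classified damage; user's accuracy not applicable", m.year)
    return AccuracyEntry(m.year, pa, ua, ta)


def mean_accuracies(per_year: Sequence[AccuracyEntry]) -> AccuracyEntry:
    """Arithmetic mean of PA / UA / TA over years (N/A entries excluded)."""
    if not per_year:
        raise ValueError("need at least one year of accuracies")

    def _mean(vals: list[float | None]) -> float | None:
        vs = [v for v in vals if v is not None]
        return sum(vs) / len(vs) if vs else None

    return AccuracyEntry(
        year=0,
        producer_pct=_mean([e.producer_pct for e in per_year]),
        user_pct=_mean([e.user_pct for e in per_year]),
        total_pct=_mean([e.total_pct for e in per_year]),
    )
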