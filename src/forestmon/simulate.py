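"""Synthetic Sentinel-2-style archive with known ground truth.

The generator emulates everything the real pipeline consumes: per-date
multiband surface-reflectance scenes (B2, B3, B4, B8 at 10 m) with a QA
cloud bitmask and a scene-level cloudy-pixel percentage; a map of forest
compartments, each with a dominant-species attribute; seasonal NDVI
phenology per species; damage events that depress NIR reflectance over
part of a compartment; and compartment-level damage reports.

Everything is a deterministic function of the configuration, including
the seed: per-scene random substreams are keyed by (seed, year,
day-of-year), so adding an acquisition date never perturbs other scenes.
The exact set of NIR-depressed pixels is exposed via
:func:`damage_truth`, so detection recall and precision can be measured
against it.

Species reflectance signatures are free parameters of the simulation
(field spectra are not part of the model); the defaults are plausible
growing-season values chosen for the five classes of the study system
(black locust, Scots pine, pedunculate oak, red oak, clearcut), with a
deciduous peak NDVI near 0.9 in midsummer.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.special import expit
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from . import grid as _grid
from .collection import Scene, SceneCollection
from .damage import DamageReport, damage_ratio
from .errors import DanglingReferenceError, SizingError
from .grid import GridSpec

#: Class legend used everywhere (codes are stable across the pipeline).
SPECIES_LEGEND: dict[int, str] = {
    0: "black_locust",
    1: "scots_pine",
    2: "pedunculate_oak",
    3: "red_oak",
    4: "clearcut",
}
CLEARCUT_CODE = 4

BAND_NAMES = ("B2", "B3", "B4", "B8")

#: Training-point class counts mirroring the field protocol
#: (black locust, Scots pine, pedunculate oak, red oak, clearcut).
TRAINING_COUNTS: dict[int, int] = {0: 15, 1: 27, 2: 40, 3: 22, 4: 19}

QA_CLOUD_VALUE = (1 << 10) | (1 << 11)  # opaque cloud + cirrus bits set together


@dataclass(frozen=True)
class PhenologyModel:
    """Seasonal NDVI curve and band signature of one species.

    NDVI follows a double-sigmoid between a dormant baseline and a summer
    peak; the fixed per-band reflectances (blue/green/red) plus the NDVI
    target determine NIR via NIR = RED * (1 + n) / (1 - n).
    """

    peak_ndvi: float
    base_ndvi: float
    greenup_doy: float
    senescence_doy: float
    width_up: float = 8.0
    width_down: float = 12.0
    noise_sd: float = 0.02
    red: float = 0.04
    green: float = 0.06
    blue: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.peak_ndvi <= 1:
            raise ValueError("peak_ndvi must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.greenup_doy >= self.senescence_doy:
            raise ValueError("green-up must precede senescence")

    def ndvi(self, doy: float) -> float:
        s = expit((doy - self.greenup_doy) / self.width_up) * expit(
            (self.senescence_doy - doy) / self.width_down
        )
        return self.base_ndvi + (self.peak_ndvi - self.base_ndvi) * s

    def reflectance(self, doy: float) -> dict[str, float]:
        """Noise-free band reflectances for one day of year."""
        n = min(self.ndvi(doy), 0.995)
        nir = self.red * (1 + n) / (1 - n)
        return {"B2": self.blue, "B3": self.green, "B4": self.red, "B8": nir}


#: Default per-species phenology/signature set (free parameters, see module docstring).
DEFAULT_PHENOLOGY: dict[int, PhenologyModel] = {
    0: PhenologyModel(0.90, 0.25, 115, 285, red=0.035, green=0.055, blue=0.025),
    1: PhenologyModel(0.80, 0.60, 100, 300, red=0.025, green=0.035, blue=0.015),
    2: PhenologyModel(0.88, 0.30, 110, 290, red=0.045, green=0.070, blue=0.030),
    3: PhenologyModel(0.84, 0.28, 112, 288, red=0.060, green=0.090, blue=0.040),
    4: PhenologyModel(0.35, 0.15, 120, 270, red=0.120, green=0.100, blue=0.080),
}

#: Bare/non-forest surface outside every compartment.
BACKGROUND = PhenologyModel(0.25, 0.12, 120, 270, red=0.100, green=0.090, blue=0.070)


@dataclass(frozen=True)
class DamageEvent:
    """One damage occurrence: which compartment, when, and how hard.

    ``severity`` is the fractional NIR reduction at affected pixels;
    ``affected_fraction`` the share of the compartment's pixels hit.
    """

    compartment_id: str
    year: int
    damage_type: str  # drought | frost | clearcut | game
    severity: float
    affected_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Compartment:
    compartment_id: str
    polygon: BaseGeometry
    species_code: int
    area_ha: float


class CompartmentSet:
    """Forest compartment polygons with species attributes."""

    def __init__(self, compartments: Sequence[Compartment]):
        self.compartments = list(compartments)
        self._by_id = {c.compartment_id: c for c in self.compartments}
        if len(self._by_id) != len(self.compartments):
            raise ValueError("compartment ids must be unique")

    def __len__(self) -> int:
        return len(self.compartments)

    def __iter__(self) -> Iterator[Compartment]:
        return iter(self.compartments)

    def __getitem__(self, i: int) -> Compartment:
        return self.compartments[i]

    def get(self, compartment_id: str) -> Compartment:
        try:
            return self._by_id[compartment_id]
        except KeyError:
            raise DanglingReferenceError(f"unknown compartment {compartment_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [c.compartment_id for c in self.compartments]

    @property
    def total_area_ha(self) -> float:
        return sum(c.area_ha for c in self.compartments)

    def label_raster(self, grid: GridSpec) -> np.ndarray:
        return _grid.label_raster([c.polygon for c in self.compartments], grid)

    def species_raster(self, grid: GridSpec) -> np.ndarray:
        """Per-pixel ground-truth species code; -1 outside all compartments."""
        labels = self.label_raster(grid)
        codes = np.array([c.species_code for c in self.compartments], dtype=np.int16)
        out = np.full(grid.shape, -1, dtype=np.int16)
        ok = labels >= 0
        out[ok] = codes[labels[ok]]
        return out


@dataclass
class SimConfig:
    """Full description of one synthetic archive."""

    grid: GridSpec
    years: tuple[int, ...]
    dates_doy: tuple[int, ...]
    n_compartments: int
    species_mixture: dict[int, float]
    phenology: dict[int, PhenologyModel] = field(default_factory=lambda: dict(DEFAULT_PHENOLOGY))
    events: tuple[DamageEvent, ...] = ()
    cloud_frac_range: tuple[float, float] = (0.0, 0.0)
    season_window: tuple[int, int] = (104, 288)  # mid-April .. mid-October, half-open
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        tot = sum(self.species_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"species mixture must sum to 1, got {tot}")
        if any(k not in SPECIES_LEGEND for k in self.species_mixture):
            raise ValueError("species mixture keys must be legend codes")
        lo, hi = self.season_window
        for d in self.dates_doy:
            if not lo <= d < hi:
                raise ValueError(f"acquisition doy {d} outside the vegetation window {self.season_window}")
        for e in self.events:
            if e.year not in self.years:
                raise ValueError(f"damage event year {e.year} outside simulated years")
        if not 0 <= self.cloud_frac_range[0] <= self.cloud_frac_range[1] <= 1:
            raise ValueError("cloud_frac_range must be 0 <= lo <= hi <= 1")


# ----------------------------------------------------------------------
# compartments


def _split_rects(width: int, height: int, n: int, rng: np.random.Generator) -> list[tuple[int, int, int, int]]:
    """Partition the (width x height) pixel grid into n rectangles by
    repeatedly splitting the largest one at a random pixel boundary."""
    rects = [(0, 0, width, height)]  # (col0, row0, w, h)
    while len(rects) < n:
        i = max(range(len(rects)), key=lambda j: rects[j][2] * rects[j][3])
        c0, r0, w, h = rects.pop(i)
        if w * h < 2:
            raise SizingError(
                f"grid too small to host {n} compartments of at least one pixel"
            )
        if w >= h and w >= 2:
            k = int(rng.integers(1, w))
            a, b = (c0, r0, k, h), (c0 + k, r0, w - k, h)
        else:
            k = int(rng.integers(1, h))
            a, b = (c0, r0, w, k), (c0, r0 + k, w, h - k)
        rects.extend([a, b])
    rects.sort(key=lambda r: (r[1], r[0]))
    return rects


def _species_counts(mixture: dict[int, float], n: int) -> dict[int, int]:
    """Deterministic class counts by largest remainder; sums exactly to n."""
    codes = sorted(mixture)
    raw = {c: mixture[c] * n for c in codes}
    counts = {c: int(math.floor(raw[c])) for c in codes}
    short = n - sum(counts.values())
    for c in sorted(codes, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    return counts


def make_compartments(config: SimConfig) -> CompartmentSet:
    """Non-overlapping rectangular compartments tiling the grid extent."""
    g = config.grid
    if config.n_compartments > g.n_pixels:
        raise SizingError(
            f"{config.n_compartments} compartments cannot each cover a pixel "
            f"of a {g.width}x{g.height} grid"
        )
    rng = np.random.default_rng([config.seed, 101])
    rects = _split_rects(g.width, g.height, config.n_compartments, rng)

    counts = _species_counts(config.species_mixture, config.n_compartments)
    codes = np.repeat(
        [c for c in sorted(counts)], [counts[c] for c in sorted(counts)]
    )
    codes = codes[rng.permutation(len(codes))]

    comps = []
    for i, (c0, r0, w, h) in enumerate(rects):
        poly = box(
            g.origin_x + c0 * g.pixel_size,
            g.origin_y - (r0 + h) * g.pixel_size,
            g.origin_x + (c0 + w) * g.pixel_size,
            g.origin_y - r0 * g.pixel_size,
        )
        comps.append(
            Compartment(
                compartment_id=f"C{i + 1:03d}",
                polygon=poly,
                species_code=int(codes[i]),
                area_ha=w * h * g.pixel_area_ha,
            )
        )
    return CompartmentSet(comps)


# ----------------------------------------------------------------------
# damage ground truth


def _event_mask(
    event: DamageEvent, compartments: CompartmentSet, labels: np.ndarray
) -> np.ndarray:
    """Pixels hit by one event: the first ceil(fraction * n) compartment
    pixels in a deterministic west-to-east sweep."""
    idx = compartments.ids.index(compartments.get(event.compartment_id).compartment_id)
    rows, cols = np.nonzero(labels == idx)
    order = np.lexsort((rows, cols))
    n_hit = math.ceil(event.affected_fraction * len(order))
    mask = np.zeros(labels.shape, dtype=bool)
    sel = order[:n_hit]
    mask[rows[sel], cols[sel]] = True
    return mask


def damage_truth(config: SimConfig, year: int) -> np.ndarray:
    """Exact boolean mask of pixels whose NIR is damage-depressed in ``year``."""
    comps = make_compartments(config)
    labels = comps.label_raster(config.grid)
    mask = np.zeros(config.grid.shape, dtype=bool)
    for e in config.events:
        if e.year == year and e.severity > 0 and e.affected_fraction > 0:
            mask |= _event_mask(e, comps, labels)
    return mask


# ----------------------------------------------------------------------
# scenes


def _cloud_field(
    grid: GridSpec, target_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Random elliptical cloud blobs covering >= target_frac of the grid."""
    mask = np.zeros(grid.shape, dtype=bool)
    if target_frac <= 0:
        return mask
    rows, cols = np.mgrid[0 : grid.height, 0 : grid.width]
    for _ in range(200):
        if mask.mean() >= target_frac:
            break
        cy, cx = rng.uniform(0, grid.height), rng.uniform(0, grid.width)
        a = rng.uniform(2.0, 6.0)
        b = rng.uniform(2.0, 6.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = rows - cy, cols - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def make_collection(config: SimConfig, year: int) -> SceneCollection:
    """One scene per configured acquisition date of ``year``.

    Reflectance = species phenology (+ per-pixel Gaussian noise), with
    that year's damage events multiplying NIR by (1 - severity) at the
    affected pixels.  Cloud blobs set QA bits 10 and 11 and drive the
    scene's cloudy-pixel-percentage metadatum exactly.
    """
    if year not in config.years:
        raise ValueError(f"year {year} not in configured years {config.years}")
    g = config.grid
    comps = make_compartments(config)
    labels = comps.label_raster(g)
    species = comps.species_raster(g)

    models = dict(config.phenology)
    pixel_model = np.full(g.shape, -1, dtype=np.int16)
    pixel_model[:] = species  # -1 keeps meaning background

    # cumulative NIR depression factor per pixel for this year
    depress = np.ones(g.shape)
    for e in config.events:
        if e.year == year:
            depress[_event_mask(e, comps, labels)] *= 1.0 - e.severity

    scenes = []
    for doy in sorted(config.dates_doy):
        rng = np.random.default_rng([config.seed, year, doy])
        bands = {b: np.empty(g.shape) for b in BAND_NAMES}
        noise_sd = np.zeros(g.shape)
        for code in list(models) + [-1]:
            model = models.get(code, BACKGROUND) if code >= 0 else BACKGROUND
            sel = pixel_model == code
            if not sel.any():
                continue
            refl = model.reflectance(doy)
            for b in BAND_NAMES:
                bands[b][sel] = refl[b]
            noise_sd[sel] = model.noise_sd
        bands["B8"] *= depress
        if (noise_sd > 0).any():
            for b in BAND_NAMES:
                bands[b] = np.clip(bands[b] + rng.normal(0.0, 1.0, g.shape) * noise_sd, 0.0, 1.0)

        target = rng.uniform(*config.cloud_frac_range) if config.cloud_frac_range[1] > 0 else 0.0
        cloud = _cloud_field(g, target, rng)
        qa = np.where(cloud, QA_CLOUD_VALUE, 0).astype(np.uint16)

        scenes.append(
            Scene(
                bands=bands,
                qa=qa,
                date=dt.date(year, 1, 1) + dt.timedelta(days=doy - 1),
                cloudy_pixel_percentage=100.0 * float(cloud.mean()),
                grid=g,
            )
        )
    return SceneCollection(scenes, grid=g, band_names=list(BAND_NAMES))


# ----------------------------------------------------------------------
# reports


def make_reports(config: SimConfig) -> list[DamageReport]:
    """One report row per damaged (compartment, year); compartment-years
    with no event have no row (downstream treats that as 0% damage)."""
    comps = make_compartments(config)
    agg: dict[tuple[str, int], dict] = {}
    for e in config.events:
        c = comps.get(e.compartment_id)  # raises on dangling ids
        key = (e.compartment_id, e.year)
        a = agg.setdefault(key, {"frac": 0.0, "types": [], "sev": 0.0})
        a["frac"] = min(1.0, a["frac"] + e.affected_fraction)
        if e.damage_type not in a["types"]:
            a["types"].append(e.damage_type)
        a["sev"] = max(a["sev"], e.severity)

    reports = []
    for (cid, year), a in sorted(agg.items()):
        comp = comps.get(cid)
        damaged = a["frac"] * comp.area_ha
        reports.append(
            DamageReport(
                compartment_id=cid,
                year=year,
                damage_type="+".join(a["types"]),
                damaged_area_ha=damaged,
                total_area_ha=comp.area_ha,
                frequency_pct=damage_ratio(damaged, comp.area_ha),
                intensity_pct=100.0 * a["sev"],
            )
        )
    return reports


# ----------------------------------------------------------------------
# ready-made study scenario


def demo_config(
    seed: int = 7,
    width: int = 60,
    height: int = 60,
    n_compartments: int = 36,
    years: tuple[int, ...] = (2017, 2018, 2019, 2020),
    damage_year: int = 2019,
    damage_area_fraction: float = 0.8,
    severity: float = 0.85,
    noise_sd: float = 0.02,
    cloud_frac_range: tuple[float, float] = (0.0, 0.05),
) -> SimConfig:
    """The default study scenario: a 4-year archive with one severe,
    widespread damage year.

    The severe year damages compartments until ``damage_area_fraction``
    of the total compartment area is affected (whole compartments,
    affected fraction 1.0) — the field situation the pipeline targets is
    a regional drought/frost event touching most of the forest.  Two
    small sub-threshold events (20% of a compartment) are placed in the
    first year to exercise the below-30% reclassification path.
    """
    phen = {c: replace(m, noise_sd=noise_sd) for c, m in DEFAULT_PHENOLOGY.items()}
    cfg = SimConfig(
        grid=GridSpec(width=width, height=height),
        years=years,
        # doys chosen to fall inside the mid-April .. mid-October window in
        # both leap and common years, so every year keeps the same dates
        dates_doy=tuple(range(105, 282, 16)),
        n_compartments=n_compartments,
        species_mixture={0: 0.15, 1: 0.20, 2: 0.35, 3: 0.20, 4: 0.10},
        phenology=phen,
        cloud_frac_range=cloud_frac_range,
        seed=seed,
    )
    comps = make_compartments(cfg)
    total = comps.total_area_ha
    events = []
    covered = 0.0
    damage_types = ("drought", "frost")
    damaged_ids = set()
    for i, c in enumerate(comps):
        if covered / total >= damage_area_fraction:
            break
        if c.species_code == CLEARCUT_CODE:
            continue  # a clearcut has no canopy to lose
        events.append(
            DamageEvent(c.compartment_id, damage_year, damage_types[i % 2], severity, 1.0)
        )
        damaged_ids.add(c.compartment_id)
        covered += c.area_ha
    minor_year = years[0]
    spare = [c for c in comps if c.compartment_id not in damaged_ids and c.species_code != CLEARCUT_CODE]
    for c in spare[:2]:
        events.append(DamageEvent(c.compartment_id, minor_year, "game", 0.3, 0.2))
    return replace(cfg, events=tuple(events))
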