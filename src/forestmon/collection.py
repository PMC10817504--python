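"""Scene collections: spatial / temporal / cloud filtering and compositing.

This is the offline counterpart of the Earth-Engine collection workflow:
``filterBounds`` -> :func:`filter_bounds`, ``filterDate`` ->
:func:`filter_date` (half-open window, the GEE convention),
``CLOUDY_PIXEL_PERCENTAGE <= p`` -> :func:`filter_cloud_metadata`, QA
bitmask masking -> :func:`mask_clouds`, and the median / mean / stdDev
reducers -> :func:`reduce`.

Nodata is represented as NaN in float band rasters.  The QA band is an
unsigned-integer bitmask in which bits 10 (opaque cloud) and 11 (cirrus)
both clear means a cloudless pixel.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

from .errors import FormatError, GridMismatchError
from .grid import GridSpec, centre_mask

log = logging.getLogger(__name__)

#: QA bit positions flagging opaque cloud and cirrus.
CLOUD_BITS: tuple[int, ...] = (10, 11)

REDUCERS = ("median", "mean", "std")


@dataclass
class Scene:
    """One acquisition date: multiband reflectance + QA bitmask + metadata."""

    bands: dict[str, np.ndarray]
    qa: np.ndarray
    date: dt.date
    cloudy_pixel_percentage: float
    grid: GridSpec

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            if arr.shape != self.grid.shape:
                raise GridMismatchError(f"band {name!r} shape {arr.shape} != grid {self.grid.shape}")
        if self.qa is not None and self.qa.shape != self.grid.shape:
            raise GridMismatchError("qa band shape does not match grid")
        if not 0 <= self.cloudy_pixel_percentage <= 100:
            raise ValueError("cloudy_pixel_percentage must be in [0, 100]")

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def copy(self) -> "Scene":
        return Scene(
            bands={k: v.copy() for k, v in self.bands.items()},
            qa=None if self.qa is None else self.qa.copy(),
            date=self.date,
            cloudy_pixel_percentage=self.cloudy_pixel_percentage,
            grid=self.grid,
        )


@dataclass
class SceneCollection:
    """An ordered stack of scenes on one shared grid."""

    scenes: list[Scene]
    grid: GridSpec | None = None
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenes:
            if self.grid is None:
                self.grid = self.scenes[0].grid
            if not self.band_names:
                self.band_names = self.scenes[0].band_names
            for s in self.scenes:
                if s.grid != self.grid:
                    raise GridMismatchError("all scenes must share one grid")
            dates = [s.date for s in self.scenes]
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValueError("scene dates must be strictly increasing")
        elif self.grid is None:
            raise ValueError("an empty collection needs an explicit grid")

    def __len__(self) -> int:
        return len(self.scenes)

    def __iter__(self) -> Iterator[Scene]:
        return iter(self.scenes)

    def __getitem__(self, i: int) -> Scene:
        return self.scenes[i]

    @property
    def dates(self) -> list[dt.date]:
        return [s.date for s in self.scenes]

    def _like(self, scenes: list[Scene]) -> "SceneCollection":
        return SceneCollection(scenes, grid=self.grid, band_names=list(self.band_names))


@dataclass
class Composite:
    """Per-pixel reduction of a (filtered, masked) collection over a period."""

    bands: dict[str, np.ndarray]
    reducer: str
    period: tuple[dt.date, dt.date] | None
    n_scenes_used: np.ndarray
    grid: GridSpec

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)


def filter_bounds(coll: SceneCollection, roi: BaseGeometry | Sequence[BaseGeometry]) -> SceneCollection:
    """Set pixels whose centre lies outside the ROI to nodata in every band."""
    if roi is None or (not isinstance(roi, BaseGeometry) and len(list(roi)) == 0):
        raise ValueError("roi must be a non-empty geometry or sequence of geometries")
    inside = centre_mask(roi, coll.grid)
    if not inside.any():
        log.warning("ROI is disjoint from the grid: every pixel becomes nodata")
    out = []
    for s in coll:
        c = s.copy()
        for arr in c.bands.values():
            arr[~inside] = np.nan
        out.append(c)
    return coll._like(out)


def filter_date(coll: SceneCollection, start: dt.date, end: dt.date) -> SceneCollection:
    """Keep scenes with start <= date < end (half-open window)."""
    if start >= end:
        raise ValueError(f"empty date window: start {start} >= end {end}")
    return coll._like([s for s in coll if start <= s.date < end])


def filter_cloud_metadata(coll: SceneCollection, max_pct: float = 5.0) -> SceneCollection:
    """Keep scenes whose scene-level cloudy-pixel percentage is <= max_pct."""
    if not 0 <= max_pct <= 100:
        raise ValueError("max_pct must be in [0, 100]")
    return coll._like([s for s in coll if s.cloudy_pixel_percentage <= max_pct])


def mask_clouds(scene: Scene, cloud_bits: Iterable[int] = CLOUD_BITS) -> Scene:
    """Nodata every band at pixels with any of the given QA bits set."""
    if scene.qa is None:
        raise FormatError("scene has no qa band; cannot mask clouds")
    bitmask = 0
    for b in cloud_bits:
        bitmask |= 1 << b
    cloudy = (scene.qa.astype(np.uint32) & bitmask) != 0
    out = scene.copy()
    for arr in out.bands.values():
        arr[cloudy] = np.nan
    return out


def mask_collection(coll: SceneCollection, cloud_bits: Iterable[int] = CLOUD_BITS) -> SceneCollection:
    """Apply :func:`mask_clouds` to every scene."""
    return coll._like([mask_clouds(s, cloud_bits) for s in coll])


def reduce(coll: SceneCollection, reducer: str) -> Composite:
    """Per-pixel, per-band reduction over valid observations.

    An observation (scene, pixel) is valid when every band is finite there.
    ``std`` is the population standard deviation (divide by n), matching
    the Earth-Engine stdDev reducer.  Pixels with zero valid observations
    are nodata in every band.
    """
    if reducer not in REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; expected one of {REDUCERS}")
    grid = coll.grid
    names = coll.band_names
    period = (min(coll.dates), max(coll.dates)) if len(coll) else None
    if not len(coll) or not names:
        n_used = np.zeros(grid.shape, dtype=np.int32)
        bands = {n: np.full(grid.shape, np.nan) for n in names}
        return Composite(bands, reducer, period, n_used, grid)

    stack = {n: np.stack([s.bands[n] for s in coll]).astype(np.float64) for n in names}
    valid = np.ones((len(coll),) + grid.shape, dtype=bool)
    for arr in stack.values():
        valid &= np.isfinite(arr)
    for arr in stack.values():
        arr[~valid] = np.nan
    n_used = valid.sum(axis=0).astype(np.int32)

    with np.errstate(invalid="ignore"):
        if reducer == "median":
            fn = np.nanmedian
        elif reducer == "mean":
            fn = np.nanmean
        else:
            fn = lambda a, axis: np.nanstd(a, axis=axis, ddof=0)  # noqa: E731
        bands = {}
        for n, arr in stack.items():
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
                bands[n] = fn(arr, axis=0)
            bands[n][n_used == 0] = np.nan
    return Composite(bands, reducer, period, n_used, grid)


def make_rgb(
    comp: Composite,
    low: float = 0.0,
    high: float = 0.3,
    rgb_bands: tuple[str, str, str] = ("B4", "B3", "B2"),
) -> np.ndarray:
    """True-colour display raster (4, H, W) uint8 RGBA.

    Reflectance is stretched linearly from [low, high] to 0..255 and
    rounded half-to-even; nodata pixels get alpha 0.
    """
    for b in rgb_bands:
        if b not in comp.bands:
            raise FormatError(f"composite lacks band {b!r} needed for RGB display")
    if high <= low:
        raise ValueError("stretch range must have high > low")
    chans = []
    alpha = np.full(comp.grid.shape, 255, dtype=np.uint8)
    for b in rgb_bands:
        v = comp.bands[b]
        scaled = np.clip((v - low) / (high - low), 0.0, 1.0) * 255.0
        nodata = ~np.isfinite(v)
        alpha[nodata] = 0
        scaled = np.where(nodata, 0.0, scaled)
        chans.append(np.rint(scaled).astype(np.uint8))
    chans.append(alpha)
    return np.stack(chans)
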