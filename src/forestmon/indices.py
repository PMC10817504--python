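"""Vegetation indices and standardized anomalies.

NDVI = (NIR - RED) / (NIR + RED), with RED = Sentinel-2 band 4 and
NIR = band 8.  The standardized anomaly

    z = (NDVI_year - NDVI_mean) / NDVI_std

is computed *per pixel* against the multi-year mean and population
standard deviation of the annual NDVI rasters, so that a year's map shows
each pixel's departure from its own baseline in baseline-sd units.
Negative z means below-baseline vitality.

Degenerate cases are nodata, never silent zeros: a pixel whose
multi-year std is 0 has no meaningful anomaly scale, and a pixel with
NIR + RED = 0 has no defined NDVI.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .collection import Composite, SceneCollection
from .errors import (
    DegenerateInputError,
    FormatError,
    GridMismatchError,
    SamplingError,
)
from .grid import GridSpec, centre_mask

log = logging.getLogger(__name__)

RED_BAND = "B4"
NIR_BAND = "B8"


@dataclass
class IndexRaster:
    """A single-band index raster (NDVI or Z-NDVI); nodata is NaN."""

    values: np.ndarray
    name: str
    label: str
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("index raster shape does not match grid")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel holds a value."""
        return np.isfinite(self.values)


def _ndvi_from_bands(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - red) / denom
    out = np.where(denom == 0, np.nan, out)
    out[~(np.isfinite(nir) & np.isfinite(red))] = np.nan
    return out


def ndvi(comp: Composite, label: str = "") -> IndexRaster:
    """NDVI of a composite; nodata where either band is nodata or NIR+RED = 0."""
    for b in (RED_BAND, NIR_BAND):
        if b not in comp.bands:
            raise FormatError(f"composite lacks band {b!r} needed for NDVI")
    values = _ndvi_from_bands(comp.bands[NIR_BAND], comp.bands[RED_BAND])
    return IndexRaster(values, "ndvi", label, comp.grid)


def multi_year_stats(annual: list[IndexRaster]) -> tuple[IndexRaster, IndexRaster]:
    """Per-pixel multi-year mean and population std of annual index rasters.

    The mean uses every year in which the pixel is valid; the std is nodata
    at pixels valid in fewer than 2 years (a 1-year 'baseline' has no
    spread).
    """
    if len(annual) < 2:
        raise ValueError("need at least 2 annual rasters for a multi-year baseline")
    grid = annual[0].grid
    for r in annual:
        if r.grid != grid:
            raise GridMismatchError("annual rasters are not on one grid")
    stack = np.stack([r.values for r in annual])
    n_valid = np.isfinite(stack).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        std = np.nanstd(stack, axis=0, ddof=0)
    mean[n_valid == 0] = np.nan
    std[n_valid < 2] = np.nan
    period = f"{annual[0].label}-{annual[-1].label}" if annual[0].label else "multi-year"
    return (
        IndexRaster(mean, "ndvi_mean", period, grid),
        IndexRaster(std, "ndvi_std", period, grid),
    )


def zndvi(year_raster: IndexRaster, mean: IndexRaster, std: IndexRaster) -> IndexRaster:
    """Standardized anomaly (x - mean) / std; nodata where any input is
    nodata or std = 0."""
    grid = year_raster.grid
    if mean.grid != grid or std.grid != grid:
        raise GridMismatchError("z-score inputs are not on one grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (year_raster.values - mean.values) / std.values
    z = np.where(std.values == 0, np.nan, z)
    return IndexRaster(z, "zndvi", year_raster.label, grid)


def median_timeseries(coll: SceneCollection, roi: BaseGeometry) -> pd.DataFrame:
    """ROI-median NDVI per scene, as a (date, median_ndvi) table.

    NDVI is computed per pixel on each scene (after whatever masking the
    caller applied); the median is over valid ROI pixels.  Scenes with no
    valid ROI pixel are omitted with a logged warning.
    """
    if roi is None or roi.is_empty:
        raise ValueError("roi must be a non-empty geometry")
    inside = centre_mask(roi, coll.grid)
    if not inside.any():
        raise ValueError("roi contains no pixel centre")
    rows = []
    for s in coll:
        v = _ndvi_from_bands(s.bands[NIR_BAND], s.bands[RED_BAND])[inside]
        v = v[np.isfinite(v)]
        if v.size == 0:
            log.warning("scene %s has no valid ROI pixel; omitted from time series", s.date)
            continue
        rows.append({"date": s.date, "median_ndvi": float(np.median(v))})
    return pd.DataFrame(rows, columns=["date", "median_ndvi"])


def normality_check(
    index: IndexRaster, n: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Shapiro-Wilk normality test on ``n`` random valid pixels.

    Pixels are sampled uniformly without replacement with a seeded
    generator; returns (W, p).
    """
    rng = np.random.default_rng(seed)
    flat = index.values.ravel()
    valid = np.flatnonzero(np.isfinite(flat))
    if valid.size < n:
        raise SamplingError(
            f"need {n} valid pixels for the normality check, found {valid.size}"
        )
    sample = flat[rng.choice(valid, size=n, replace=False)]
    if np.ptp(sample) == 0:
        raise DegenerateInputError("constant sample; Shapiro-Wilk is undefined")
    log.debug("normality check: n=%d seed=%s", n, seed)
    w, p = stats.shapiro(sample)
    return float(w), float(p)
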