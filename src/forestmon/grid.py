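"""Raster grid geometry.

All rasters in the pipeline live on a north-up, axis-aligned grid of square
pixels (10 m by default, the Sentinel-2 10 m band resolution).  ``origin_x``
/ ``origin_y`` are the map coordinates of the *top-left corner* of the
top-left pixel; row indices increase southward, column indices eastward —
the usual GeoTIFF convention.

The pixel-in-polygon rule used everywhere (region-of-interest filtering,
damage-report rasterization, zonal statistics) is *centre containment*: a
pixel belongs to a polygon iff the polygon contains the pixel's centre
point.  One rule, applied consistently, keeps pixel counts exact and makes
zonal areas additive over non-overlapping polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid (shape, pixel size, placement, CRS label)."""

    width: int
    height: int
    pixel_size: float = 10.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must be at least 1x1 pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every pixel centre as (X, Y) arrays of shape (H, W)."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def pixel_centre(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.pixel_size,
            self.origin_y - (row + 0.5) * self.pixel_size,
        )

    def point_to_pixel(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the pixel containing the point, or None if outside."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        if 0 <= row < self.height and 0 <= col < self.width:
            return row, col
        return None

    def extent_polygon(self) -> BaseGeometry:
        return box(
            self.origin_x,
            self.origin_y - self.height * self.pixel_size,
            self.origin_x + self.width * self.pixel_size,
            self.origin_y,
        )

    def pixel_polygon(self, row: int, col: int) -> BaseGeometry:
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return box(x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def centre_mask(geom: BaseGeometry | Sequence[BaseGeometry], grid: GridSpec) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centre lies inside the geometry.

    Accepts a single geometry or a sequence (interpreted as their union).
    """
    if not isinstance(geom, BaseGeometry):
        geom = shapely.union_all(list(geom))
    X, Y = grid.pixel_centres()
    return shapely.contains_xy(geom, X, Y)


def label_raster(geoms: Sequence[BaseGeometry], grid: GridSpec) -> np.ndarray:
    """Rasterize non-overlapping polygons to an int32 label grid.

    Pixel value is the index of the polygon containing the pixel centre,
    or -1 outside all polygons.  If polygons overlap (they should not in a
    compartment map), the lowest index wins — deterministic.
    """
    out = np.full(grid.shape, -1, dtype=np.int32)
    X, Y = grid.pixel_centres()
    for i, g in enumerate(geoms):
        hit = shapely.contains_xy(g, X, Y) & (out == -1)
        out[hit] = i
    return out
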