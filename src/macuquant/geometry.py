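"""Fovea-centered region geometry for macular thickness and angiography maps.

The analysis grid is a square raster with an isotropic millimetre scale and a
(possibly fractional) fovea center.  All regional measurements — the central
0.60 mm circle, the 2.50 mm total annular zone (TAZ), the six concentric
rings C1–C6 that partition the TAZ, and the four 90° quadrant sectors
(superior / temporal / inferior / nasal) — are defined on this grid and
shared between the thickness and capillary-density modules.

Pixel rule: a pixel belongs to a region iff its *center* does; radial
intervals are half-open ``[inner, outer)`` so that concentric rings partition
the annulus exactly, pixel for pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Central avascular circle diameter (mm); also the fixed FAZ disk.
CENTRAL_DIAMETER_MM = 0.60
#: Outer diameter of the total annular zone (mm).
TAZ_OUTER_DIAMETER_MM = 2.50
#: Outer diameters of the six concentric rings partitioning the TAZ (mm).
RING_DIAMETERS_MM: Tuple[float, ...] = (0.92, 1.23, 1.55, 1.87, 2.18, 2.50)
RING_NAMES: Tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6")
SECTOR_NAMES: Tuple[str, ...] = ("S", "T", "I", "N")
#: All region names reported for a capillary-density profile.
RCD_REGION_NAMES: Tuple[str, ...] = ("TAZ",) + RING_NAMES + SECTOR_NAMES
#: Region names reported for thickness maps.
THICKNESS_REGION_NAMES: Tuple[str, ...] = ("C", "TAZ", "S", "T", "I", "N")

#: Default image side on which the temporal retina lies in fundus orientation.
DEFAULT_TEMPORAL_SIDE = {"OD": "left", "OS": "right"}


@dataclass(frozen=True)
class FoveaCenteredGrid:
    """Square raster with mm scale and fovea center.

    Parameters
    ----------
    height, width : int
        Raster shape in pixels.
    mm_per_pixel : float
        Isotropic pixel pitch in millimetres.
    center_row, center_col : float
        Fovea center in pixel coordinates (fractional allowed, 0-based,
        pixel-center convention).
    laterality : str, optional
        "OD" (right eye) or "OS" (left eye); required only for sector masks.
    """

    height: int
    width: int
    mm_per_pixel: float
    center_row: float
    center_col: float
    laterality: Optional[str] = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if not (0 <= self.center_row <= self.height - 1):
            raise ValueError("center_row outside image bounds")
        if not (0 <= self.center_col <= self.width - 1):
            raise ValueError("center_col outside image bounds")
        if self.laterality is not None and self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @classmethod
    def for_enface(
        cls,
        size_px: int = 1024,
        field_of_view_mm: float = 3.0,
        laterality: Optional[str] = None,
        center: Optional[Tuple[float, float]] = None,
    ) -> "FoveaCenteredGrid":
        """Grid for an en face angiogram: square, fovea at the image center."""
        if center is None:
            center = ((size_px - 1) / 2.0, (size_px - 1) / 2.0)
        return cls(size_px, size_px, field_of_view_mm / size_px,
                   center[0], center[1], laterality)

    def radius_mm(self) -> np.ndarray:
        """Distance of every pixel center from the fovea center, in mm."""
        rows = np.arange(self.height)[:, None] - self.center_row
        cols = np.arange(self.width)[None, :] - self.center_col
        return np.hypot(rows, cols) * self.mm_per_pixel

    def angle_deg(self) -> np.ndarray:
        """Polar angle of every pixel: 0° = image up, increasing clockwise."""
        dy = self.center_row - np.arange(self.height)[:, None]  # up positive
        dx = np.arange(self.width)[None, :] - self.center_col   # right positive
        return np.degrees(np.arctan2(dx, dy)) % 360.0

    def max_inscribed_radius_mm(self) -> float:
        """Largest radius fully contained in the image (pixel centers)."""
        return min(self.center_row, self.center_col,
                   self.height - 1 - self.center_row,
                   self.width - 1 - self.center_col) * self.mm_per_pixel


@dataclass
class RegionMask:
    """A named binary region on a fovea-centered grid."""

    grid: FoveaCenteredGrid
    name: str
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.grid.height, self.grid.width):
            raise ValueError("mask shape does not match grid")
        self.pixels = self.pixels.astype(bool)

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.pixels))

    @property
    def area_mm2(self) -> float:
        return self.pixel_count * self.grid.mm_per_pixel ** 2

    def to_png(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, (self.pixels.astype(np.uint8) * 255))


def make_annulus_mask(
    grid: FoveaCenteredGrid,
    inner_d: float,
    outer_d: float,
    name: str = "annulus",
) -> RegionMask:
    """Annulus ``inner_d/2 <= r < outer_d/2`` (mm) about the fovea center.

    ``inner_d = 0`` yields a filled circle.  Raises if the annulus is empty
    (``inner_d >= outer_d``) or extends past the image border.
    """
    if inner_d < 0:
        raise ValueError("inner diameter must be non-negative")
    if inner_d >= outer_d:
        raise ValueError("inner diameter must be strictly smaller than outer")
    overflow = outer_d / 2.0 - grid.max_inscribed_radius_mm()
    if overflow > 0:
        raise ValueError(
            f"annulus of outer diameter {outer_d:g} mm extends "
            f"{overflow:.3f} mm beyond the image border"
        )
    r = grid.radius_mm()
    return RegionMask(grid, name, (r >= inner_d / 2.0) & (r < outer_d / 2.0))


def make_central_mask(grid: FoveaCenteredGrid) -> RegionMask:
    """The central 0.60 mm diameter circle (region C / fixed FAZ disk)."""
    return make_annulus_mask(grid, 0.0, CENTRAL_DIAMETER_MM, "C")


def make_taz_mask(grid: FoveaCenteredGrid) -> RegionMask:
    """The total annular zone: 2.50 mm disk minus the 0.60 mm FAZ disk."""
    return make_annulus_mask(grid, CENTRAL_DIAMETER_MM,
                             TAZ_OUTER_DIAMETER_MM, "TAZ")


def make_ring_series(grid: FoveaCenteredGrid) -> Dict[str, RegionMask]:
    """The six concentric rings C1..C6 partitioning the TAZ."""
    diameters = (CENTRAL_DIAMETER_MM,) + RING_DIAMETERS_MM
    return {
        name: make_annulus_mask(grid, diameters[k], diameters[k + 1], name)
        for k, name in enumerate(RING_NAMES)
    }


def make_sector_masks(
    grid: FoveaCenteredGrid,
    inner_d: float = CENTRAL_DIAMETER_MM,
    outer_d: float = TAZ_OUTER_DIAMETER_MM,
    temporal_side: Optional[str] = None,
) -> Dict[str, RegionMask]:
    """Quadrant sectors S/T/I/N of the annulus, split by the 45° diagonals.

    Superior is the "up" quadrant, inferior the "down" quadrant.  Temporal
    and nasal are resolved from the grid's laterality assuming fundus
    display orientation, or forced with ``temporal_side`` ("left"/"right").
    """
    if temporal_side is None:
        if grid.laterality is None:
            raise ValueError("laterality required to assign temporal/nasal sectors")
        temporal_side = DEFAULT_TEMPORAL_SIDE[grid.laterality]
    if temporal_side not in ("left", "right"):
        raise ValueError("temporal_side must be 'left' or 'right'")

    annulus = make_annulus_mask(grid, inner_d, outer_d).pixels
    ang = grid.angle_deg()
    up = (ang >= 315.0) | (ang < 45.0)
    right = (ang >= 45.0) & (ang < 135.0)
    down = (ang >= 135.0) & (ang < 225.0)
    left = (ang >= 225.0) & (ang < 315.0)
    temporal, nasal = (left, right) if temporal_side == "left" else (right, left)
    return {
        "S": RegionMask(grid, "S", annulus & up),
        "T": RegionMask(grid, "T", annulus & temporal),
        "I": RegionMask(grid, "I", annulus & down),
        "N": RegionMask(grid, "N", annulus & nasal),
    }


def standard_region_masks(
    grid: FoveaCenteredGrid, temporal_side: Optional[str] = None
) -> Dict[str, RegionMask]:
    """All named regions: C, TAZ, C1..C6, and the four quadrant sectors."""
    masks: Dict[str, RegionMask] = {
        "C": make_central_mask(grid),
        "TAZ": make_taz_mask(grid),
    }
    masks.update(make_ring_series(grid))
    masks.update(make_sector_masks(grid, temporal_side=temporal_side))
    return masks


def region_table(masks: Sequence[RegionMask]) -> pd.DataFrame:
    """Summary table of region geometry for export."""
    diameters = dict(zip(RING_NAMES, zip((CENTRAL_DIAMETER_MM,) + RING_DIAMETERS_MM[:-1],
                                         RING_DIAMETERS_MM)))
    diameters["C"] = (0.0, CENTRAL_DIAMETER_MM)
    diameters["TAZ"] = (CENTRAL_DIAMETER_MM, TAZ_OUTER_DIAMETER_MM)
    for s in SECTOR_NAMES:
        diameters[s] = (CENTRAL_DIAMETER_MM, TAZ_OUTER_DIAMETER_MM)
    rows = [
        {
            "name": m.name,
            "inner_mm": diameters.get(m.name, (np.nan, np.nan))[0],
            "outer_mm": diameters.get(m.name, (np.nan, np.nan))[1],
            "area_mm2": m.area_mm2,
            "pixel_count": m.pixel_count,
        }
        for m in masks
    ]
    return pd.DataFrame(rows)
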