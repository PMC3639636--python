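"""Core data containers shared across the pipeline.

Coordinate conventions
----------------------
Global images: origin at the top-left pixel, ``x`` = column, ``y`` = row,
0-based.  Physical coordinates are millimetres, with ``x_mm = col / scale``.
Angles are measured counterclockwise from +x (in the array frame) and damage
orientations live in ``[0, 180)`` degrees, since a scratch has no head or tail.

Height maps: same array convention, physical coordinates in micrometres
(``x_um = col * pitch``).  Heights ``z`` are micrometres, positive above the
nominal surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


def normalize_orientation(deg: float) -> float:
    """Fold an angle in degrees into the scratch-orientation range [0, 180)."""
    return float(deg) % 180.0


@dataclass
class GlobalImage:
    """Calibrated grayscale photograph of one view of a bearing surface.

    Parameters
    ----------
    pixels : ndarray
        2-D intensity raster, floats in [0, 1] (8-bit input is rescaled on
        load).
    scale : float
        Linear pixels per millimetre.  The default imaging protocol works at
        4432 px/mm^2, i.e. ~66.6 px/mm linear.
    view_id : str
        Label of the photographic view (polar, or one of the 30-degree
        circumferential increments).
    sector_mask : ndarray of bool
        Analyzable region of this view; pixels outside are ignored by every
        stage.  Defaults to the full frame.
    """

    pixels: np.ndarray
    scale: float
    view_id: str = "view0"
    sector_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if not self.scale > 0:
            raise ValueError("scale must be positive (pixels per mm)")
        if self.sector_mask is None:
            self.sector_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.sector_mask = np.asarray(self.sector_mask, dtype=bool)
            if self.sector_mask.shape != self.pixels.shape:
                raise ValueError("sector_mask shape must match pixels")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the frame in millimetres."""
        h, w = self.pixels.shape
        return w / self.scale, h / self.scale


@dataclass
class HeightMap:
    """Areal optical-profilometry scan.

    ``z`` is in micrometres; ``pitch`` is the lateral sampling interval in
    micrometres per pixel (instrument maximum 0.25 um^2/px, i.e. 0.5 um
    pitch).  ``valid_mask`` marks measured pixels; interferometric dropouts
    are simply excluded rather than inpainted.
    """

    z: np.ndarray
    pitch: float = 0.5
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be a 2-D raster")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive (um per pixel)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.z.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.z.shape:
                raise ValueError("valid_mask shape must match z")
        if not np.all(np.isfinite(self.z[self.valid_mask])):
            raise ValueError("z must be finite wherever valid_mask is set")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def extent_um(self) -> tuple[float, float]:
        h, w = self.z.shape
        return w * self.pitch, h * self.pitch


@dataclass
class ScratchSegment:
    """Straight-line scratch segment in the global (mm) frame.

    Curvilinear scratches are discretized into concatenations of these.
    ``lip_height`` (h_L, um) and ``peak_samples`` are populated by the
    profilometry stage; until then they are ``None``.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    lip_height: float | None = None
    peak_samples: list[float] = field(default_factory=list)
    feature_id: int = -1
    width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment must have positive length")

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def orientation(self) -> float:
        """Orientation in degrees, CCW from +x, folded into [0, 180)."""
        ang = math.degrees(
            math.atan2(self.p1[1] - self.p0[1], self.p1[0] - self.p0[0])
        )
        return normalize_orientation(ang)


@dataclass
class ScrapeRegion:
    """Polygon-delineated diffuse-damage feature in the global (mm) frame.

    ``Ra`` (um) and ``micro_direction`` (prevailing microscratch orientation
    inside the scrape) are populated by the profilometry stage.
    ``macro_direction`` is the orientation of the polygon's principal axis and
    is available immediately after segmentation.
    """

    polygon: list[tuple[float, float]]
    Ra: float | None = None
    micro_direction: float | None = None
    feature_id: int = -1

    def __post_init__(self) -> None:
        poly = self.shapely
        if not poly.is_valid or poly.is_empty:
            raise ValueError("scrape polygon must be simple and non-empty")
        if poly.area <= 0:
            raise ValueError("scrape polygon must have positive area")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def area(self) -> float:
        """Polygon area in mm^2 (shoelace, via shapely)."""
        return float(self.shapely.area)

    @property
    def macro_direction(self) -> float:
        """Principal-axis orientation of the polygon in [0, 180) degrees.

        Computed from the second moments of the polygon's vertices weighted
        by the boundary; for elongated scrapes this tracks the macro axis.
        """
        poly = self.shapely
        # second central moments of the polygon region via a dense sample of
        # its exterior is fragile; use the minimum rotated rectangle instead
        rect = poly.minimum_rotated_rectangle
        coords = list(rect.exterior.coords)[:4]
        best = None
        for a, b in zip(coords, coords[1:] + coords[:1]):
            length = math.hypot(b[0] - a[0], b[1] - a[1])
            if best is None or length > best[0]:
                best = (length, math.degrees(math.atan2(b[1] - a[1], b[0] - a[0])))
        return normalize_orientation(best[1])
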