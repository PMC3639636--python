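"""Conversion of measured damage severity into wear-coefficient elevation.

Pin-on-plate experiments relate counterface damage severity to the elevation
of the Archard wear coefficient of the polyethylene articulating against it:

* scratches follow a saturating exponential in lip height h_L (um):
      k_inc = 58.0985 * (1 - exp(-0.2237 * h_L))
* scrapes follow a power law in average roughness Ra (um):
      k_inc = 37.538 * Ra**1.2

Scratches with lips below about 1 um produce no detectable wear acceleration
and can be Boolean-masked away before simulation.  Per-feature k_inc values
are rasterized onto a wear grid by max-composition (overlap never double
counts) with a floor of 1: an "elevation" field never predicts less wear
than the undamaged baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.draw import polygon2mask
from skimage.morphology import dilation, footprint_rectangle

from .types import ScratchSegment, ScrapeRegion

CELL_NONE, CELL_SCRATCH, CELL_SCRAPE = 0, 1, 2


@dataclass
class WearParams:
    """Constants of the severity-to-wear-elevation relations.

    ``A_scratch`` (dimensionless) and ``b_scratch`` (1/um) parameterize the
    exponential scratch law; ``C_scrape`` (dimensionless, Ra in um) and
    ``p_scrape`` the scrape power law.  ``lip_threshold`` (um) is the lip
    height below which a scratch is wear-inconsequential.  ``k0`` is the
    baseline Archard wear coefficient in mm/(MPa*mm).
    """

    A_scratch: float = 58.0985
    b_scratch: float = 0.2237
    C_scrape: float = 37.538
    p_scrape: float = 1.2
    lip_threshold: float = 1.0
    k0: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("A_scratch", "b_scratch", "C_scrape", "p_scrape", "lip_threshold", "k0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def kinc_scratch(h_L: float, params: WearParams | None = None) -> float:
    """Wear-coefficient scaling factor for a scratch of lip height h_L (um).

    Strictly increasing from 0 at h_L = 0, saturating at ``A_scratch``
    (58.0985 by default) as h_L grows.
    """
    p = params or WearParams()
    h = np.asarray(h_L, dtype=float)
    if np.any(h < 0):
        raise ValueError("lip height must be >= 0")
    out = p.A_scratch * (1.0 - np.exp(-p.b_scratch * h))
    return float(out) if np.isscalar(h_L) else out


def kinc_scrape(Ra: float, params: WearParams | None = None) -> float:
    """Wear-coefficient scaling factor for a scrape of roughness Ra (um)."""
    p = params or WearParams()
    r = np.asarray(Ra, dtype=float)
    if np.any(r < 0):
        raise ValueError("Ra must be >= 0")
    out = p.C_scrape * r**p.p_scrape
    return float(out) if np.isscalar(Ra) else out


def mask_inconsequential(
    segments: list[ScratchSegment], threshold: float = 1.0
) -> list[ScratchSegment]:
    """Drop scratches whose lip height falls below the wear threshold.

    Returns a new list; the input is untouched.  Segments without a measured
    lip height are an error — masking happens after metrology.
    """
    for s in segments:
        if s.lip_height is None:
            raise ValueError(f"segment {s.feature_id} has no measured lip height")
    return [s for s in segments if s.lip_height >= threshold]


@dataclass
class GridSpec:
    """Raster layout of the wear grid: ``shape`` cells of ``cell_size_mm``,
    with the cell (0, 0) top-left corner at ``origin_mm``."""

    shape: tuple[int, int]
    cell_size_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def to_cells(self, pts_mm: np.ndarray) -> np.ndarray:
        """mm points -> fractional (col, row) cell coordinates."""
        pts = np.atleast_2d(pts_mm)
        return (pts - np.asarray(self.origin_mm)) / self.cell_size_mm


@dataclass
class KincField:
    """Gridded wear-coefficient scaling factors plus provenance.

    ``grid`` cells are >= 1 everywhere; cells untouched by damage are exactly
    1.  ``provenance`` holds the id of the winning feature per cell (-1 for
    none) and ``cell_class`` its class (0 none / 1 scratch / 2 scrape), which
    downstream wear attribution uses.  Feature directionality (scratch
    orientation, scrape micro direction) is carried alongside in
    ``direction_deg`` for provenance but does not modulate k_inc.
    """

    grid: np.ndarray
    spec: GridSpec
    provenance: np.ndarray
    cell_class: np.ndarray
    direction_deg: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.grid < 1.0):
            raise ValueError("k_inc field cells must be >= 1")


DirectionModulation = Callable[[float, float], float]
"""Hook modulating k_inc by feature direction: f(kinc, direction_deg) -> kinc.

No functional form for the direction dependence of the wear factor is
established for this encoding; the default is the identity.  The hook exists
so a directional wear law can be plugged in without touching rasterization.
"""


def _identity_modulation(kinc: float, direction_deg: float) -> float:
    return kinc


def rasterize_kinc(
    segments: list[ScratchSegment],
    scrapes: list[ScrapeRegion],
    spec: GridSpec,
    params: WearParams | None = None,
    direction_modulation: DirectionModulation | None = None,
) -> KincField:
    """Paint per-feature k_inc values onto the wear grid (max composition).

    Scratch footprints are the segment rasterized at its measured width
    (minimum one cell); scrape footprints are the filled polygon.  A cell
    overlapped by several features takes the largest k_inc, so adding a
    feature can never lower a cell.  Values below 1 are clamped to 1 in the
    field (raw per-feature values remain available via the k_inc functions).
    Features falling outside the grid are clipped with a warning.
    """
    import warnings

    p = params or WearParams()
    mod = direction_modulation or _identity_modulation
    h, w = spec.shape
    grid = np.ones(spec.shape, dtype=float)
    prov = np.full(spec.shape, -1, dtype=int)
    cls = np.zeros(spec.shape, dtype=np.uint8)
    direc = np.full(spec.shape, np.nan)

    def paint(mask: np.ndarray, value: float, fid: int, fclass: int, direction: float):
        take = mask & (value > grid)
        grid[take] = value
        prov[take] = fid
        cls[take] = fclass
        direc[take] = direction

    from skimage.draw import line as draw_line

    for s in segments:
        if s.lip_height is None:
            raise ValueError(f"segment {s.feature_id} has no measured lip height")
        (c0, r0), (c1, r1) = spec.to_cells(np.array([s.p0, s.p1]))
        mask = np.zeros(spec.shape, dtype=bool)
        rr0, cc0 = int(round(r0)), int(round(c0))
        rr1, cc1 = int(round(r1)), int(round(c1))
        rr, cc = draw_line(rr0, cc0, rr1, cc1)
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        if not inside.all():
            warnings.warn(f"scratch {s.feature_id} extends outside the grid; clipped")
        mask[rr[inside], cc[inside]] = True
        width_cells = 1
        if s.width_mm is not None:
            width_cells = max(int(round(s.width_mm / spec.cell_size_mm)), 1)
        if width_cells > 1:
            mask = dilation(mask, footprint_rectangle((width_cells, width_cells)))
        value = max(mod(kinc_scratch(s.lip_height, p), s.orientation), 1.0)
        paint(mask, value, s.feature_id, CELL_SCRATCH, s.orientation)

    for s in scrapes:
        if s.Ra is None:
            raise ValueError(f"scrape {s.feature_id} has no measured Ra")
        cells = spec.to_cells(np.array(s.polygon))
        if cells.min() < -1e-9 or np.any(cells.max(axis=0) > [w, h]):
            warnings.warn(f"scrape {s.feature_id} extends outside the grid; clipped")
        verts = np.column_stack([cells[:, 1], cells[:, 0]])  # (row, col)
        mask = polygon2mask(spec.shape, verts)
        direction = s.micro_direction if s.micro_direction is not None else s.macro_direction
        value = max(mod(kinc_scrape(s.Ra, p), direction), 1.0)
        paint(mask, value, s.feature_id, CELL_SCRAPE, direction)

    return KincField(grid=grid, spec=spec, provenance=prov, cell_class=cls, direction_deg=direc)
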