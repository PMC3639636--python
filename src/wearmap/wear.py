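"""Simplified Archard wear integrator on the damage-encoded grid.

Local linear wear depth per step is the product of contact pressure, sliding
increment, and the wear coefficient ``k0 * k_inc`` — the baseline coefficient
elevated wherever the polyethylene is overpassed by counterface damage.
Accumulation is quasi-static: the contact fields are prescribed, surface
geometry is not updated, so depth after N identical cycles is exactly N times
one cycle.  This is deliberately a stand-in for a full FE contact model; the
quantity of interest is the *fold increase* of wear caused by the encoded
damage, which the scheme reproduces exactly (per-cell damaged/baseline depth
ratio equals the cell's k_inc wherever the baseline wears at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .encoding import CELL_SCRATCH, CELL_SCRAPE, KincField, WearParams


@dataclass
class KinematicCycle:
    """Prescribed per-step contact fields for one loading cycle.

    ``pressure``: (steps, h, w) MPa; ``sliding``: (steps, h, w) mm of sliding
    increment; ``sliding_direction``: degrees per cell, stored for provenance
    only (no cross-shear law is applied).
    """

    pressure: np.ndarray
    sliding: np.ndarray
    sliding_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.sliding = np.asarray(self.sliding, dtype=float)
        if self.pressure.ndim == 2:
            self.pressure = self.pressure[None]
        if self.sliding.ndim == 2:
            self.sliding = self.sliding[None]
        if self.pressure.shape != self.sliding.shape:
            raise ValueError("pressure and sliding shapes must match")
        if np.any(self.pressure < 0) or np.any(self.sliding < 0):
            raise ValueError("pressure and sliding must be >= 0")

    @property
    def steps(self) -> int:
        return self.pressure.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pressure.shape[1:]


@dataclass
class WearResult:
    """Accumulated linear wear ``depth`` (um) and total ``volume`` (mm^3)."""

    depth: np.ndarray
    volume: float
    cycles: int
    cell_area_mm2: float

    def __post_init__(self) -> None:
        if np.any(self.depth < 0):
            raise ValueError("wear depth must be >= 0")


def archard_step(
    kinc: KincField, p: np.ndarray, s: np.ndarray, params: WearParams | None = None
) -> np.ndarray:
    """Depth increment (mm) for one step: dd = k0 * k_inc * p * s.

    Zero wherever pressure or sliding vanish; bilinear in pressure and
    sliding scales.
    """
    prm = params or WearParams()
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    if p.shape != kinc.grid.shape or s.shape != kinc.grid.shape:
        raise ValueError("pressure/sliding shape must match the k_inc grid")
    return prm.k0 * kinc.grid * p * s


def run_cycles(
    kinc: KincField,
    cycle: KinematicCycle,
    n_cycles: int,
    params: WearParams | None = None,
) -> WearResult:
    """Accumulate wear over ``n_cycles`` identical cycles (quasi-static)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if cycle.grid_shape != kinc.grid.shape:
        raise ValueError("cycle grids must match the k_inc grid")
    depth_mm = np.zeros(kinc.grid.shape, dtype=np.float64)
    for step in range(cycle.steps):
        depth_mm += archard_step(kinc, cycle.pressure[step], cycle.sliding[step], params)
    depth_mm *= float(n_cycles)
    cell_area = kinc.spec.cell_size_mm**2
    volume = float(depth_mm.sum() * cell_area)
    return WearResult(
        depth=depth_mm * 1000.0,  # um
        volume=volume,
        cycles=int(n_cycles),
        cell_area_mm2=cell_area,
    )


@dataclass
class FoldIncrease:
    """Damage-induced wear amplification and its per-class attribution.

    ``fold`` is the ratio of damaged to baseline wear volume.  The *excess*
    volume (damaged - baseline) is attributed to scratch vs scrape cells via
    the k_inc field's provenance; the two fractions sum to 1 whenever any
    excess exists.
    """

    fold: float
    scratch_fraction: float
    scrape_fraction: float


def wear_fold_increase(
    damaged: WearResult, baseline: WearResult, kinc: KincField | None = None
) -> FoldIncrease:
    """Fold increase of total wear volume vs the undamaged baseline."""
    if damaged.depth.shape != baseline.depth.shape or damaged.cycles != baseline.cycles:
        raise ValueError("results must share grid and cycle count")
    if baseline.volume <= 0:
        raise ValueError("baseline wear volume is zero")
    fold = damaged.volume / baseline.volume
    scratch_frac = scrape_frac = 0.0
    if kinc is not None:
        excess = (damaged.depth - baseline.depth) * damaged.cell_area_mm2 / 1000.0
        total_excess = float(excess.sum())
        if total_excess > 0:
            scratch_frac = float(excess[kinc.cell_class == CELL_SCRATCH].sum()) / total_excess
            scrape_frac = float(excess[kinc.cell_class == CELL_SCRAPE].sum()) / total_excess
    return FoldIncrease(fold=fold, scratch_fraction=scratch_frac, scrape_fraction=scrape_frac)


def hertz_patch(
    grid_shape: tuple[int, int],
    cell_size_mm: float,
    peak_pressure_mpa: float,
    patch_radius_mm: float,
    center_path_mm: list[tuple[float, float]],
) -> KinematicCycle:
    """Demo kinematics: a hemispherical (Hertzian) pressure patch translated
    along a path; each path step contributes its length as sliding increment.

    p(r) = p0 * sqrt(1 - (r/a)^2) inside radius ``a``, zero outside.  A
    single-point path (no motion) yields zero sliding and hence zero wear.
    Path points outside the grid are clipped with a warning.
    """
    import warnings

    if patch_radius_mm <= 0:
        raise ValueError("patch radius must be positive")
    h, w = grid_shape
    extent = (w * cell_size_mm, h * cell_size_mm)
    path = []
    for x, y in center_path_mm:
        cx, cy = x, y
        if not (0 <= x <= extent[0] and 0 <= y <= extent[1]):
            warnings.warn("path point outside grid; clipped")
            cx = min(max(x, 0.0), extent[0])
            cy = min(max(y, 0.0), extent[1])
        path.append((cx, cy))

    rr, cc = np.mgrid[0:h, 0:w]
    xs = (cc + 0.5) * cell_size_mm
    ys = (rr + 0.5) * cell_size_mm

    steps = max(len(path) - 1, 1)
    pressure = np.zeros((steps, h, w))
    sliding = np.zeros((steps, h, w))
    direction = np.zeros((steps, h, w))
    if len(path) == 1:
        cx, cy = path[0]
        r = np.hypot(xs - cx, ys - cy)
        pressure[0] = peak_pressure_mpa * np.sqrt(
            np.clip(1.0 - (r / patch_radius_mm) ** 2, 0.0, None)
        )
        return KinematicCycle(pressure=pressure, sliding=sliding, sliding_direction=direction)

    for k in range(steps):
        (x0, y0), (x1, y1) = path[k], path[k + 1]
        step_len = math.hypot(x1 - x0, y1 - y0)
        # pressure evaluated at the midpoint of the step
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        r = np.hypot(xs - cx, ys - cy)
        pressure[k] = peak_pressure_mpa * np.sqrt(
            np.clip(1.0 - (r / patch_radius_mm) ** 2, 0.0, None)
        )
        sliding[k] = step_len
        direction[k] = math.degrees(math.atan2(y1 - y0, x1 - x0)) % 180.0
    return KinematicCycle(pressure=pressure, sliding=sliding, sliding_direction=direction)
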