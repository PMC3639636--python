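"""Profilometry metrology: form removal, roughness parameters, scratch lip
height, microscratch direction, and sampling-convergence analysis.

All heights are micrometres.  Lateral coordinates within a scan are
micrometres with ``x = col * pitch``, ``y = row * pitch`` (origin top-left).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, transform
from skimage.draw import polygon2mask

from .types import HeightMap, ScratchSegment, normalize_orientation


class DegenerateSurfaceError(ValueError):
    """Form fit impossible: too few or collinear valid pixels."""


class IsotropicTextureError(ValueError):
    """No dominant microscratch line found in a scrape scan."""


@dataclass
class RoughnessSummary:
    """Standard areal roughness parameters over a region.

    Ra = mean |z - mean(z)| (average roughness);
    Rp = max(z - mean(z))   (peak asperity height);
    Rv = |min(z - mean(z))| (maximum asperity depth, reported positive).
    """

    Ra: float
    Rp: float
    Rv: float
    n_pixels: int


def remove_form(hm: HeightMap) -> HeightMap:
    """Fit and subtract the global quadric form from the raw scan.

    The nominal bearing surface is a sphere; over a few-mm patch its sag is
    captured to sub-0.02 um accuracy by the full bivariate quadric
    ``z = a + bx + cy + dx^2 + exy + fy^2``, fit by least squares over valid
    pixels and subtracted.  The residual map has zero-mean fit error, so
    local damage relief (lips, grooves, scrape texture) remains.
    Idempotent: the quadric fit of a form-removed map is ~0.
    """
    valid = hm.valid_mask
    if valid.sum() < 6:
        raise DegenerateSurfaceError("need >= 6 valid pixels for a quadric fit")
    h, w = hm.shape
    rr, cc = np.mgrid[0:h, 0:w]
    # center/scale the coordinates for conditioning
    x = (cc - (w - 1) / 2.0) / max(w, 1)
    y = (rr - (h - 1) / 2.0) / max(h, 1)
    xv, yv = x[valid], y[valid]
    A = np.column_stack(
        [np.ones_like(xv), xv, yv, xv**2, xv * yv, yv**2]
    )
    if np.linalg.matrix_rank(A) < 6:
        raise DegenerateSurfaceError("valid pixels are degenerate (e.g. collinear)")
    coef, *_ = np.linalg.lstsq(A, hm.z[valid], rcond=None)
    form = (
        coef[0]
        + coef[1] * x
        + coef[2] * y
        + coef[3] * x**2
        + coef[4] * x * y
        + coef[5] * y**2
    )
    z = hm.z - form
    return HeightMap(z=z, pitch=hm.pitch, valid_mask=valid.copy())


def roughness_params(hm: HeightMap, region=None) -> RoughnessSummary:
    """Areal roughness parameters over ``region`` (or the full valid map).

    ``region`` may be a boolean raster, a shapely polygon in um coordinates,
    or a vertex list in um.  Heights are referenced to the mean surface
    height within the region, matching the areal definition of Ra as the
    average absolute height difference of pixels relative to the regional
    mean.
    """
    if region is None:
        mask = hm.valid_mask
    elif isinstance(region, np.ndarray) and region.dtype == bool:
        mask = region & hm.valid_mask
    else:
        coords = getattr(region, "exterior", None)
        verts_um = list(coords.coords) if coords is not None else list(region)
        verts = np.array([(y / hm.pitch, x / hm.pitch) for x, y in verts_um])
        mask = polygon2mask(hm.shape, verts) & hm.valid_mask
    vals = hm.z[mask]
    if vals.size < 2:
        raise ValueError("region must contain at least 2 valid pixels")
    dev = vals - vals.mean()
    return RoughnessSummary(
        Ra=float(np.abs(dev).mean()),
        Rp=float(dev.max()),
        Rv=float(-dev.min()),
        n_pixels=int(vals.size),
    )


def _bilinear(hm: HeightMap, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
    """Bilinearly interpolated heights at um coordinates."""
    coords = np.vstack([y_um / hm.pitch, x_um / hm.pitch])
    return ndimage.map_coordinates(hm.z, coords, order=1, mode="nearest")


def scratch_lip_height(
    hm: HeightMap,
    seg: ScratchSegment,
    spacing: float = 10.0,
    half_width: float = 25.0,
    n_transect: int = 51,
) -> tuple[float, list[float]]:
    """Scratch lip height h_L from perpendicular sampling lines.

    The (form-removed) scan is queried along equally spaced sampling lines
    perpendicular to the scratch segment, each of total length
    ``2 * half_width`` um.  The peak surface height on each line is taken
    (the groove only contributes negative values after form removal, so the
    lips dominate), and h_L is the mean of the per-line peaks.  Sampling
    lines that would leave the scan are dropped; at least 3 valid lines are
    required.

    ``seg`` endpoints are in the scan frame, in um.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    x0, y0 = seg.p0
    x1, y1 = seg.p1
    L = math.hypot(x1 - x0, y1 - y0)
    n_lines = max(int(math.floor(L / spacing)) + 1, 1)
    ts = np.linspace(0.0, 1.0, n_lines)
    ux, uy = (x1 - x0) / L, (y1 - y0) / L
    nx, ny = -uy, ux
    offs = np.linspace(-half_width, half_width, n_transect)

    w_um, h_um = hm.extent_um()
    peaks: list[float] = []
    for t in ts:
        cx, cy = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        xs = cx + offs * nx
        ys = cy + offs * ny
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w_um - hm.pitch or ys.max() > h_um - hm.pitch:
            continue  # clipped at scan border: drop the whole line
        peaks.append(float(_bilinear(hm, xs, ys).max()))
    if len(peaks) < 3:
        raise ValueError("fewer than 3 sampling lines fall inside the scan")
    return float(np.mean(peaks)), peaks


def convergence_study(
    hm: HeightMap,
    seg: ScratchSegment,
    spacings: list[float],
    half_width: float = 25.0,
    rel_tol: float = 0.01,
) -> pd.DataFrame:
    """Lip height vs sampling-line spacing, to pick an adequate density.

    ``spacings`` must be sorted descending (coarse to fine).  The returned
    table reports h_L per spacing, the successive change |dh_L|, the
    deviation from the finest-spacing estimate, and a ``converged`` flag on
    the coarsest spacing whose estimate agrees with the finest within
    ``rel_tol`` (relative, with a 1e-3 um absolute floor for near-zero lips).
    """
    if sorted(spacings, reverse=True) != list(spacings):
        raise ValueError("spacings must be sorted descending")
    h_vals = [scratch_lip_height(hm, seg, s, half_width)[0] for s in spacings]
    finest = h_vals[-1]
    dh = [float("nan")] + [abs(b - a) for a, b in zip(h_vals, h_vals[1:])]
    dev = [abs(h - finest) for h in h_vals]
    tol = max(rel_tol * abs(finest), 1e-3)
    converged = [False] * len(spacings)
    if len(spacings) > 1:
        for i, d in enumerate(dev):
            if d < tol:
                converged[i] = True
                break
    return pd.DataFrame(
        {
            "spacing_um": spacings,
            "h_L_um": h_vals,
            "delta_um": dh,
            "dev_from_finest_um": dev,
            "converged": converged,
        }
    )


def microscratch_direction(
    hm: HeightMap,
    gradient_percentile: float = 90.0,
    min_line_frac: float = 0.5,
) -> float:
    """Prevailing microscratch orientation inside a scrape scan, in [0, 180).

    The form-removed height map is binarized on Sobel gradient magnitude
    (threshold at ``gradient_percentile``), then a classic Hough line search
    finds the longest straight track; its orientation is the scraping
    direction.  Ties are broken by larger accumulator count, then smaller
    angle.  If no accumulator peak reaches ``min_line_frac`` of the largest
    traversable line length, the texture is declared isotropic and
    :class:`IsotropicTextureError` is raised (callers typically fall back to
    the scrape's macro direction).
    """
    if hm.z.size == 0:
        raise ValueError("empty height map")
    grad = filters.sobel(hm.z)
    thresh = np.percentile(grad, gradient_percentile)
    binary = grad > thresh
    theta = np.deg2rad(np.arange(0.0, 180.0, 0.5) - 90.0)
    hspace, angles, dists = transform.hough_line(binary, theta=theta)
    min_count = min_line_frac * min(hm.shape)
    peaks = transform.hough_line_peaks(
        hspace, angles, dists, num_peaks=5, threshold=min_count
    )
    candidates = list(zip(*peaks))
    if not candidates:
        raise IsotropicTextureError("no dominant line: isotropic scrape texture")
    # hough_line's angle is the normal direction; the line runs perpendicular
    best = max(
        candidates,
        key=lambda c: (c[0], -normalize_orientation(math.degrees(c[1]) + 90.0)),
    )
    return normalize_orientation(math.degrees(best[1]) + 90.0)
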