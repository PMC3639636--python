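"""Synthetic phantoms: global images and profilometry height maps with known
ground-truth damage.

Every downstream stage (segmentation, registration, metrology, encoding,
wear) is exercised against phantoms because no deposited retrieval imagery
exists.  The phantom embeds two damage classes on a spherical bearing form:

* **scratches** — thin linear grooves flanked by raised lips.  The height
  profile across a scratch is modeled as a negative Gaussian groove with two
  positive Gaussian lips at the groove edges.  Real scratch cross-sections
  are not published for this instrumentation, so the Gaussian profile is a
  stand-in chosen for smoothness and analytic control of the lip peak; see
  docs/methods.md.  By default the groove depth is set so that displaced
  groove volume equals lip volume (volume-conserving ploughing).
* **scrapes** — polygonal patches of band-limited roughness, optionally with
  an anisotropic set of parallel micro-grooves along a stated microscratch
  direction.  The texture is rescaled so the realized Ra of the patch equals
  the requested target.

Heights are quantized to 0.01 um, the instrument's out-of-plane resolution.
Identical truth + seed + parameters give bit-identical rasters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .types import GlobalImage, HeightMap, normalize_orientation

Z_QUANTUM_UM = 0.01  # instrument vertical resolution

# grayscale contrast model: damage is darker than the polished background
BACKGROUND_INTENSITY = 0.90
SCRATCH_CONTRAST = 0.3  # scratch intensity = 0.3 x background
SCRAPE_CONTRAST = 0.6   # scrape intensity = 0.6 x background


@dataclass
class ScratchTruth:
    """Ground truth for one straight scratch segment.

    ``p0``/``p1`` in mm (global frame); ``width_um`` is the groove breadth;
    ``lip_height_um`` the height of the flanking ridges above the nominal
    surface; ``groove_depth_um=None`` selects the volume-conserving depth.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    lip_height_um: float = 2.0
    width_um: float = 30.0
    groove_depth_um: float | None = None

    @property
    def orientation(self) -> float:
        return normalize_orientation(
            math.degrees(math.atan2(self.p1[1] - self.p0[1], self.p1[0] - self.p0[0]))
        )

    @property
    def length_mm(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


@dataclass
class ScrapeTruth:
    """Ground truth for one polygonal scrape patch."""

    polygon: list[tuple[float, float]]  # mm
    target_ra_um: float = 0.5
    micro_direction_deg: float | None = None  # None -> isotropic texture

    @property
    def macro_direction_deg(self) -> float:
        poly = Polygon(self.polygon)
        rect = poly.minimum_rotated_rectangle
        coords = list(rect.exterior.coords)[:4]
        best = (0.0, 0.0)
        for a, b in zip(coords, coords[1:] + coords[:1]):
            length = math.hypot(b[0] - a[0], b[1] - a[1])
            if length > best[0]:
                best = (length, math.degrees(math.atan2(b[1] - a[1], b[0] - a[0])))
        return normalize_orientation(best[1])


@dataclass
class DamageTruth:
    """Complete phantom specification: damage features + spherical form."""

    scratches: list[ScratchTruth] = field(default_factory=list)
    scrapes: list[ScrapeTruth] = field(default_factory=list)
    sphere_radius_mm: float = 14.0  # 28 mm femoral head
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.scratches:
            if s.lip_height_um < 0:
                raise ValueError("lip heights must be >= 0")
            if s.width_um <= 0:
                raise ValueError("scratch width must be positive")
        for s in self.scrapes:
            if not s.target_ra_um > 0:
                raise ValueError("Ra targets must be positive")
            poly = Polygon(s.polygon)
            if not poly.is_valid:
                raise ValueError("scrape polygons must be simple")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _segment_distance_field(shape, p0_px, p1_px):
    """Per-pixel distance (px) to a segment, and axial coordinate along it."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = cc.astype(float)
    py = rr.astype(float)
    dx, dy = p1_px[0] - p0_px[0], p1_px[1] - p0_px[1]
    L2 = dx * dx + dy * dy
    t = ((px - p0_px[0]) * dx + (py - p0_px[1]) * dy) / max(L2, 1e-12)
    tc = np.clip(t, 0.0, 1.0)
    qx = p0_px[0] + tc * dx
    qy = p0_px[1] + tc * dy
    return np.hypot(px - qx, py - qy), t


def _polygon_mask(shape, polygon_px) -> np.ndarray:
    from skimage.draw import polygon2mask

    # polygon2mask expects (row, col) vertex order
    verts = np.array([(y, x) for x, y in polygon_px])
    return polygon2mask(shape, verts)


def gen_global_phantom(
    truth: DamageTruth,
    extent_mm: tuple[float, float] = (5.0, 5.0),
    scale: float = 40.0,
    noise_sd: float = 0.01,
) -> tuple[GlobalImage, dict]:
    """Render a diffused-light style global image of the phantom.

    Returns the image plus per-feature boolean label masks
    ``{"scratch": [m0, ...], "scrape": [m0, ...]}`` in raster frame.  Where a
    scratch crosses a scrape, the scrape wins (both in the drawn image and in
    the label masks), mirroring the downstream rule that scrape regions are
    removed from the scratch mask.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(truth.seed)
    w_px = int(round(extent_mm[0] * scale))
    h_px = int(round(extent_mm[1] * scale))
    shape = (h_px, w_px)
    img = np.full(shape, BACKGROUND_INTENSITY, dtype=float)

    scrape_masks = []
    for s in truth.scrapes:
        poly_px = [(x * scale, y * scale) for x, y in s.polygon]
        m = _polygon_mask(shape, poly_px)
        scrape_masks.append(m)
    scrape_union = (
        np.any(scrape_masks, axis=0) if scrape_masks else np.zeros(shape, bool)
    )

    scratch_masks = []
    for s in truth.scratches:
        p0 = (s.p0[0] * scale, s.p0[1] * scale)
        p1 = (s.p1[0] * scale, s.p1[1] * scale)
        dist, _ = _segment_distance_field(shape, p0, p1)
        # thin dark line: at least 2 px across so edge detection has support
        half_width = max(s.width_um / 1000.0 * scale / 2.0, 1.0)
        m = dist <= half_width
        m &= ~scrape_union  # scrape wins
        scratch_masks.append(m)

    for m in scratch_masks:
        img[m] = BACKGROUND_INTENSITY * SCRATCH_CONTRAST
    for m in scrape_masks:
        img[m] = BACKGROUND_INTENSITY * SCRAPE_CONTRAST
    if scrape_masks:
        # speckle inside scrapes: diffuse darkening is not uniform
        speckle = rng.normal(0.0, 0.04, size=shape)
        img[scrape_union] += speckle[scrape_union]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    gimg = GlobalImage(pixels=img, scale=scale, view_id=f"phantom-{truth.seed}")
    return gimg, {"scratch": scratch_masks, "scrape": scrape_masks}


def _calibrated_lip_amplitude(
    lip_height: float, groove_depth: float, sigma_g: float, sigma_l: float, c: float
) -> float:
    """Lip Gaussian amplitude A such that the transverse profile

        f(d) = -D exp(-d^2/2sg^2) + A [exp(-(d-c)^2/2sl^2) + exp(-(d+c)^2/2sl^2)]

    peaks at exactly ``lip_height``.  Monotone in A, solved by bisection.
    """
    if lip_height == 0:
        return 0.0
    d = np.linspace(0.0, c + 5 * sigma_l, 2001)

    def peak(A):
        f = (
            -groove_depth * np.exp(-(d**2) / (2 * sigma_g**2))
            + A * np.exp(-((d - c) ** 2) / (2 * sigma_l**2))
            + A * np.exp(-((d + c) ** 2) / (2 * sigma_l**2))
        )
        return f.max()

    lo, hi = 0.0, 2.0 * lip_height + groove_depth
    while peak(hi) < lip_height:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if peak(mid) < lip_height:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _scratch_relief(shape, pitch, s: ScratchTruth) -> np.ndarray:
    """Height relief (um) of one scratch on a height-map grid."""
    p0 = (s.p0[0] * 1000.0 / pitch, s.p0[1] * 1000.0 / pitch)
    p1 = (s.p1[0] * 1000.0 / pitch, s.p1[1] * 1000.0 / pitch)
    dist_px, t = _segment_distance_field(shape, p0, p1)
    d = dist_px * pitch  # um from scratch axis

    sigma_g = s.width_um / 4.0
    sigma_l = max(s.width_um / 6.0, 2.0)
    c = s.width_um / 2.0  # lips sit at the groove edges
    if s.groove_depth_um is None:
        # volume-conserving ploughing: groove area = lip area per unit length,
        # solved jointly with the lip-peak calibration (two fixed-point passes
        # converge well below the 0.01 um height quantum)
        D = s.lip_height_um
        for _ in range(8):
            A = _calibrated_lip_amplitude(s.lip_height_um, D, sigma_g, sigma_l, c)
            D = 2.0 * A * sigma_l / sigma_g
    else:
        D = s.groove_depth_um
        A = _calibrated_lip_amplitude(s.lip_height_um, D, sigma_g, sigma_l, c)

    profile = (
        -D * np.exp(-(d**2) / (2 * sigma_g**2))
        + A * np.exp(-((d - c) ** 2) / (2 * sigma_l**2))
        + A * np.exp(-((d + c) ** 2) / (2 * sigma_l**2))
    )
    # taper smoothly to zero beyond the segment ends
    end_dist = np.zeros(shape)
    over = (t < 0) | (t > 1)
    if np.any(over):
        # distance beyond the nearer endpoint, in um
        seg_len = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
        axial = np.where(t < 0, -t, t - 1.0) * seg_len * pitch
        end_dist[over] = axial[over]
    taper = np.exp(-(end_dist**2) / (2 * (s.width_um / 2.0) ** 2))
    return profile * taper


def _scrape_relief(shape, pitch, s: ScrapeTruth, rng) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean scrape texture scaled to the target Ra; returns (z, mask)."""
    poly_px = [(x * 1000.0 / pitch, y * 1000.0 / pitch) for x, y in s.polygon]
    mask = _polygon_mask(shape, poly_px)
    if not mask.any():
        return np.zeros(shape), mask

    # band-limited isotropic roughness: smoothed white noise
    noise = rng.normal(0.0, 1.0, size=shape)
    texture = ndimage.gaussian_filter(noise, sigma=3.0)

    if s.micro_direction_deg is not None:
        # parallel micro-grooves along the stated direction: a quasi-periodic
        # negative ridge set, phase-jittered so it looks worn rather than ruled
        theta = math.radians(s.micro_direction_deg)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        # signed distance along the normal of the groove direction (um)
        u = (-math.sin(theta) * cc + math.cos(theta) * rr) * pitch
        period = 24.0  # um between micro-grooves
        grooves = -np.clip(np.cos(2 * np.pi * u / period), 0.0, None) ** 4
        texture = 0.35 * texture + 1.2 * grooves

    vals = texture[mask]
    vals = vals - vals.mean()
    ra = np.abs(vals).mean()
    if ra > 0:
        vals *= s.target_ra_um / ra
    z = np.zeros(shape)
    z[mask] = vals
    return z, mask


def sphere_cap(shape, pitch, radius_mm, center_px=None) -> np.ndarray:
    """Height (um) of a spherical cap sampled on the height-map grid.

    z = R - sqrt(R^2 - r^2), negated so the cap apex is the highest point,
    then shifted so the apex is at z = 0 (the profilometer measures relative
    heights anyway; the quadric form fit removes any offset).
    """
    if center_px is None:
        center_px = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r_um = np.hypot(cc - center_px[0], rr - center_px[1]) * pitch
    R_um = radius_mm * 1000.0
    return -(R_um - np.sqrt(np.maximum(R_um**2 - r_um**2, 0.0)))


def gen_heightmap_phantom(
    truth: DamageTruth,
    pitch: float = 1.0,
    extent_mm: tuple[float, float] = (1.0, 1.0),
    quantize: bool = True,
) -> tuple[HeightMap, DamageTruth]:
    """Render a profilometry scan of the phantom: sphere form + damage relief.

    ``pitch`` is um/px; ``extent_mm`` is the scanned area (instrument
    stitching supports up to ~5 mm x 5 mm).  Scratch/scrape coordinates in
    ``truth`` are interpreted in the same mm frame as the global phantom, so
    the identity mm->mm mapping (scaled to um) registers the two.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if extent_mm[0] <= 0 or extent_mm[1] <= 0:
        raise ValueError("extent must be positive")
    if max(extent_mm) > 5.0 + 1e-9:
        raise ValueError("extent exceeds the ~5 mm x 5 mm stitching limit")

    rng = np.random.default_rng(truth.seed + 1)
    w_px = int(round(extent_mm[0] * 1000.0 / pitch))
    h_px = int(round(extent_mm[1] * 1000.0 / pitch))
    shape = (h_px, w_px)

    relief = np.zeros(shape)
    for s in truth.scratches:
        relief += _scratch_relief(shape, pitch, s)
    for s in truth.scrapes:
        z, _ = _scrape_relief(shape, pitch, s, rng)
        relief += z

    z = relief + sphere_cap(shape, pitch, truth.sphere_radius_mm)
    if quantize:
        z = np.round(z / Z_QUANTUM_UM) * Z_QUANTUM_UM
    return HeightMap(z=z, pitch=pitch), truth
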