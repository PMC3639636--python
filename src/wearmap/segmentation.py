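"""Global-image damage detection: scratches vs scrapes.

The pipeline mirrors standard practice for diffused-light photographs of
retrieved bearing surfaces:

1. Canny edge detection flags all grayscale discontinuities relative to the
   bright undamaged background (fine scratches included).
2. A square median filter (default 20 x 20 px) blurs away thin linear
   features; what remains dark is *diffuse* damage.
3. Dark regions of the filtered image are autosegmented by an intensity
   threshold and polygonized: these are the scrape features.
4. Scrape regions are removed from the pre-median-filter Canny result; the
   remaining edges are classified as scratch damage.
5. A Hough transform discretizes the scratch mask into straight-line
   segments; curvilinear scratches become concatenations of segments.

Every detected damage pixel therefore belongs to exactly one class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union
from skimage import feature, measure, morphology, transform
from skimage.draw import polygon2mask

from .types import GlobalImage, ScratchSegment, ScrapeRegion


@dataclass
class DetectConfig:
    """Analyst-settable parameters of the detection pipeline."""

    canny_sigma: float = 2.0
    canny_low: float | None = None   # None -> percentile-based per image
    canny_high: float | None = None
    median_size: int = 20
    scrape_threshold: float | None = None  # None -> 0.82 x background mode
    min_scrape_area_mm2: float = 0.05
    min_length_mm: float = 0.3
    theta_res_deg: float = 1.0
    rho_res_px: float = 1.0
    max_gap_px: int = 3
    hough_threshold: int = 10
    merge_angle_deg: float = 3.0
    merge_offset_px: float = 6.0  # must exceed the Canny double-edge spacing
    scrape_dilation_px: float = 5.0  # margin when clearing scrape boundary edges
    close_radius_px: int = 3  # closes the Canny double-edge pair before thinning
    seed: int = 0


def canny_damage_edges(
    img: GlobalImage,
    sigma: float = 2.0,
    low: float | None = None,
    high: float | None = None,
    min_gradient: float = 0.05,
) -> np.ndarray:
    """Boolean edge raster of damage boundaries, restricted to the sector mask.

    ``low``/``high`` are hysteresis thresholds on gradient magnitude (image
    intensities are in [0, 1]).  When omitted they are set per image from
    gradient-magnitude percentiles, standing in for the analyst-set value;
    ``min_gradient`` floors the automatic threshold so sensor noise on an
    undamaged surface (gradients well below real damage contrast) is never
    flagged.
    """
    if low is not None and high is not None:
        if not (high >= low > 0):
            raise ValueError("need high >= low > 0")
    if low is None or high is None:
        gm = ndimage.gaussian_gradient_magnitude(img.pixels, sigma=sigma)
        gmax = float(gm.max())
        if gmax <= 0:
            return np.zeros(img.shape, dtype=bool)
        if high is None:
            high = max(float(np.percentile(gm, 99.0)), min_gradient)
        if low is None:
            low = 0.4 * high
    edges = feature.canny(
        img.pixels, sigma=sigma, low_threshold=low, high_threshold=high
    )
    return edges & img.sector_mask


def median_suppress(img: GlobalImage, size: int = 20) -> GlobalImage:
    """Median-filter the image so thin linear features vanish.

    Replaces each pixel with the median of the surrounding ``size x size``
    square.  Linear features narrower than about half the filter size are
    restored to background; broad (scrape) regions survive.
    """
    if not (isinstance(size, (int, np.integer)) and size >= 1):
        raise ValueError("size must be an integer >= 1")
    if size == 1:
        filtered = img.pixels.copy()
    else:
        filtered = ndimage.median_filter(img.pixels, size=int(size), mode="nearest")
    return GlobalImage(
        pixels=filtered,
        scale=img.scale,
        view_id=img.view_id,
        sector_mask=img.sector_mask,
    )


def segment_scrapes(
    filtered: GlobalImage,
    intensity_threshold: float | None = None,
    min_area_mm2: float = 0.05,
) -> list[ScrapeRegion]:
    """Autosegment dark regions of the median-filtered image into scrapes.

    Connected components below ``intensity_threshold`` (within the sector
    mask) are polygonized; components smaller than ``min_area_mm2`` are
    treated as speckle and dropped.  Polygons are in mm, global frame.
    """
    if intensity_threshold is None:
        # analyst default: a bit below the background mode
        background = float(np.median(filtered.pixels[filtered.sector_mask]))
        intensity_threshold = 0.82 * background
    if not (0.0 <= intensity_threshold <= 1.0):
        raise ValueError("intensity threshold outside the [0, 1] range")

    dark = (filtered.pixels < intensity_threshold) & filtered.sector_mask
    labels, n = ndimage.label(dark)
    regions: list[ScrapeRegion] = []
    scale = filtered.scale
    min_area_px = min_area_mm2 * scale * scale
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_area_px:
            continue
        # pad so boundary contours close even at the image border
        padded = np.pad(comp, 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) - 1.0  # undo padding
        poly_mm = [(c / scale, r / scale) for r, c in contour]
        poly = Polygon(poly_mm)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        poly = poly.simplify(0.5 / scale, preserve_topology=True)
        if poly.area < min_area_mm2:
            continue
        regions.append(ScrapeRegion(polygon=list(poly.exterior.coords)))
    regions.sort(key=lambda r: -r.area)
    for k, r in enumerate(regions):
        r.feature_id = k
    return regions


def scrape_pixel_mask(shape, scrapes: list[ScrapeRegion], scale: float) -> np.ndarray:
    """Rasterize scrape polygons (mm) onto a pixel grid."""
    mask = np.zeros(shape, dtype=bool)
    for s in scrapes:
        verts = np.array([(y * scale, x * scale) for x, y in s.polygon])
        mask |= polygon2mask(shape, verts)
    return mask


def scratch_mask(
    edges: np.ndarray,
    scrapes: list[ScrapeRegion],
    scale: float,
    dilation_px: float = 0.0,
) -> np.ndarray:
    """Remove scrape interiors from the edge raster; what remains is scratch.

    ``dilation_px`` grows the scrape regions by a small margin before removal
    so that the Canny edges *of the scrape boundary itself* (which straddle
    the polygon outline) are not misclassified as scratches.
    """
    if not scrapes:
        return edges.copy()
    region = scrape_pixel_mask(edges.shape, scrapes, scale)
    if dilation_px > 0:
        region = morphology.dilation(region, morphology.disk(int(round(dilation_px))))
    return edges & ~region


def thin_scratch_mask(
    mask: np.ndarray, close_radius_px: int = 3, split_junctions: bool = True
) -> np.ndarray:
    """Collapse each scratch's Canny double-edge pair onto a 1-px centerline.

    Edge detection outlines both sides of a thin dark line; morphological
    closing fills the sliver between the pair and skeletonization reduces the
    filled band to its centerline, so the Hough stage sees one track per
    scratch.  Where scratches cross, the skeleton forms a junction through
    which the line search would otherwise fit spurious bridging chords;
    ``split_junctions`` blanks a small neighbourhood around every skeleton
    point with more than two neighbours, severing the branches (the straight
    halves of each crossing track are re-joined by collinear merging).
    """
    if close_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius_px))
    skel = morphology.skeletonize(mask)
    if split_junctions:
        neighbours = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3)), mode="constant")
        junctions = skel & (neighbours > 3)  # self + more than 2 branches
        if junctions.any():
            clearance = morphology.dilation(junctions, morphology.disk(2))
            skel = skel & ~clearance
    return skel


def _merge_collinear(
    segments: list[tuple[tuple[float, float], tuple[float, float]]],
    angle_tol_deg: float,
    offset_tol_px: float,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Merge nearly collinear, overlapping segments (px frame).

    Canny produces two parallel edges for each thin dark line and the
    probabilistic Hough transform often re-detects fragments of the same
    track, so duplicates are unified here.  Two segments merge when their
    orientations differ by < ``angle_tol_deg``, their perpendicular offset is
    < ``offset_tol_px``, and their axial extents overlap or nearly touch.
    Merging is transitive (union-find); each group is replaced by the segment
    spanning the extreme projections onto the group's mean direction.
    """
    n = len(segments)
    if n <= 1:
        return list(segments)

    def angle_of(seg):
        (x0, y0), (x1, y1) = seg
        return math.degrees(math.atan2(y1 - y0, x1 - x0)) % 180.0

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    angs = [angle_of(s) for s in segments]
    lens = [math.hypot(s[1][0] - s[0][0], s[1][1] - s[0][1]) for s in segments]
    for i in range(n):
        for j in range(i + 1, n):
            dang = abs(angs[i] - angs[j])
            dang = min(dang, 180.0 - dang)
            # short fragments carry noisier angles: loosen the tolerance to
            # the angle subtended by the offset tolerance over their length,
            # but never past 2x the base tolerance (genuinely distinct
            # orientations, e.g. successive chords of an arc, must survive)
            ang_tol = max(
                angle_tol_deg,
                min(
                    math.degrees(math.atan2(1.5 * offset_tol_px, min(lens[i], lens[j]))),
                    2.0 * angle_tol_deg,
                ),
            )
            if dang >= ang_tol:
                continue
            (x0, y0), (x1, y1) = segments[i]
            ux, uy = x1 - x0, y1 - y0
            L = lens[i]
            ux, uy = ux / L, uy / L
            nx, ny = -uy, ux
            # perpendicular offsets and axial extents of segment j w.r.t. i
            offs, axs = [], []
            for (px, py) in segments[j]:
                offs.append((px - x0) * nx + (py - y0) * ny)
                axs.append((px - x0) * ux + (py - y0) * uy)
            if min(abs(o) for o in offs) >= offset_tol_px and abs(
                sum(offs) / 2
            ) >= offset_tol_px:
                continue
            lo, hi = min(axs), max(axs)
            gap_tol = 0.25 * L + 2.0 * offset_tol_px
            if hi < -gap_tol or lo > L + gap_tol:
                continue
            union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(segments[members[0]])
            continue
        # mean direction weighted by length (axial, sign-folded)
        sx = sy = 0.0
        for i in members:
            (x0, y0), (x1, y1) = segments[i]
            a = math.radians(angs[i] * 2.0)
            L = math.hypot(x1 - x0, y1 - y0)
            sx += L * math.cos(a)
            sy += L * math.sin(a)
        mean_ang = math.atan2(sy, sx) / 2.0
        ux, uy = math.cos(mean_ang), math.sin(mean_ang)
        pts = [p for i in members for p in segments[i]]
        cx = sum(p[0] for p in pts) / len(pts)
        cy = sum(p[1] for p in pts) / len(pts)
        proj = [((p[0] - cx) * ux + (p[1] - cy) * uy) for p in pts]
        lo, hi = min(proj), max(proj)
        merged.append(
            (
                (cx + lo * ux, cy + lo * uy),
                (cx + hi * ux, cy + hi * uy),
            )
        )
    return merged


def _point_to_segment_dist(px, py, seg):
    (x0, y0), (x1, y1) = seg
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    t = ((px - x0) * dx + (py - y0) * dy) / max(L2, 1e-12)
    t = min(max(t, 0.0), 1.0)
    return math.hypot(px - (x0 + t * dx), py - (y0 + t * dy))


def _suppress_covered(
    segments: list[tuple[tuple[float, float], tuple[float, float]]],
    offset_tol_px: float,
    coverage_frac: float = 0.8,
    n_samples: int = 21,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Drop short segments that longer ones already explain.

    Where scratches cross, the skeleton's junction spawns spur chords that
    bridge between tracks; such a spur lies almost entirely inside the
    corridor (perpendicular distance < ``offset_tol_px``) of the longer
    detected segments.  Segments are visited longest-first and a candidate is
    dropped when >= ``coverage_frac`` of points sampled along it fall inside
    an already-kept segment's corridor.
    """
    order = sorted(
        segments,
        key=lambda s: -math.hypot(s[1][0] - s[0][0], s[1][1] - s[0][1]),
    )
    kept: list = []
    ts = np.linspace(0.0, 1.0, n_samples)
    for seg in order:
        (x0, y0), (x1, y1) = seg
        covered = 0
        for t in ts:
            px, py = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
            if any(
                _point_to_segment_dist(px, py, k) < offset_tol_px for k in kept
            ):
                covered += 1
        if kept and covered / n_samples >= coverage_frac:
            continue
        kept.append(seg)
    return kept


def hough_scratch_segments(
    mask: np.ndarray,
    scale: float,
    min_length_mm: float = 0.3,
    theta_res_deg: float = 1.0,
    rho_res_px: float = 1.0,
    max_gap_px: int = 3,
    threshold: int = 10,
    merge_angle_deg: float = 3.0,
    merge_offset_px: float = 6.0,
    seed: int = 0,
) -> list[ScratchSegment]:
    """Discretize the scratch mask into straight-line segments (mm frame).

    A probabilistic Hough transform extracts candidate straight lines whose
    supported length exceeds ``min_length_mm``; near-duplicates (the two
    Canny edges of one scratch, overlapping re-detections) are merged.
    Curvilinear tracks come back as concatenations of straight segments.

    ``rho_res_px`` is part of the analyst surface for symmetry with the
    classic accumulator transform (see
    :func:`wearmap.profilometry.microscratch_direction`); the probabilistic
    extractor votes at native 1-px rho resolution, so values other than 1
    are ignored here.
    """
    if min_length_mm <= 0:
        raise ValueError("min_length must be positive")
    if not mask.any():
        return []
    min_len_px = max(int(round(min_length_mm * scale)), 2)
    theta = np.linspace(
        -np.pi / 2, np.pi / 2, max(int(round(180.0 / theta_res_deg)), 2), endpoint=False
    )
    lines = transform.probabilistic_hough_line(
        mask,
        threshold=threshold,
        line_length=min_len_px,
        line_gap=max_gap_px,
        theta=theta,
        rng=seed,
    )
    if not lines:
        return []
    segs = [((float(x0), float(y0)), (float(x1), float(y1))) for (x0, y0), (x1, y1) in lines]
    segs = _merge_collinear(segs, merge_angle_deg, merge_offset_px)
    segs = _suppress_covered(segs, merge_offset_px)
    out = []
    for (x0, y0), (x1, y1) in segs:
        p0 = (x0 / scale, y0 / scale)
        p1 = (x1 / scale, y1 / scale)
        if math.hypot(p1[0] - p0[0], p1[1] - p0[1]) < min_length_mm:
            continue
        out.append(ScratchSegment(p0=p0, p1=p1))
    out.sort(key=lambda s: (-s.length, s.orientation))
    for k, s in enumerate(out):
        s.feature_id = k
    return out


def _clip_segments_to_scrapes(
    segments: list[ScratchSegment],
    scrapes: list[ScrapeRegion],
    min_length_mm: float,
) -> list[ScratchSegment]:
    """Truncate scratch segments at scrape boundaries (scrape wins)."""
    if not scrapes:
        return segments
    union = unary_union([s.shapely for s in scrapes])
    out = []
    for seg in segments:
        line = LineString([seg.p0, seg.p1])
        diff = line.difference(union)
        parts = (
            [diff]
            if diff.geom_type == "LineString"
            else list(getattr(diff, "geoms", []))
        )
        for part in parts:
            if part.is_empty or part.length < min_length_mm:
                continue
            coords = list(part.coords)
            out.append(
                ScratchSegment(p0=tuple(coords[0]), p1=tuple(coords[-1]))
            )
    for k, s in enumerate(out):
        s.feature_id = k
    return out


def detect_damage(
    img: GlobalImage, config: DetectConfig | None = None
) -> tuple[list[ScratchSegment], list[ScrapeRegion]]:
    """Full detection pipeline: edges -> median -> scrapes -> scratches.

    Returns disjoint feature sets: no scratch segment point lies strictly
    inside any scrape polygon.
    """
    cfg = config or DetectConfig()
    edges = canny_damage_edges(
        img, sigma=cfg.canny_sigma, low=cfg.canny_low, high=cfg.canny_high
    )
    filtered = median_suppress(img, size=cfg.median_size)
    scrapes = segment_scrapes(
        filtered, cfg.scrape_threshold, min_area_mm2=cfg.min_scrape_area_mm2
    )
    smask = scratch_mask(edges, scrapes, img.scale, dilation_px=cfg.scrape_dilation_px)
    smask = thin_scratch_mask(smask, close_radius_px=cfg.close_radius_px)
    segments = hough_scratch_segments(
        smask,
        img.scale,
        min_length_mm=cfg.min_length_mm,
        theta_res_deg=cfg.theta_res_deg,
        rho_res_px=cfg.rho_res_px,
        max_gap_px=cfg.max_gap_px,
        threshold=cfg.hough_threshold,
        merge_angle_deg=cfg.merge_angle_deg,
        merge_offset_px=cfg.merge_offset_px,
        seed=cfg.seed,
    )
    segments = _clip_segments_to_scrapes(segments, scrapes, cfg.min_length_mm)
    return segments, scrapes
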