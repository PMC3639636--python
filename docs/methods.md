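# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `wearmap`, and what the phantom-based validation does and does not
demonstrate about real retrieval data.

## Damage taxonomy and coordinate conventions

Damage on a hard bearing counterface is treated as two classes. A *scratch*
is a thin linear track: a groove ploughed into the surface, flanked by raised
lips whose height h_L (μm above the nominal surface) is the dominant driver
of polyethylene wear acceleration. A *scrape* is a broad patch of diffuse
damage — dense microscratching that cannot be resolved into individual tracks
at global-image resolution — characterized by its areal average roughness Ra
and by the prevailing orientation of the microscratches within it, which need
not coincide with the patch's macroscopic axis (edge-loaded dislocation
scrapes are the classic counterexample).

All rasters use origin top-left, x = column, y = row, 0-based. Global-image
coordinates are millimetres (`x_mm = col / scale`, default scale 66.6 px/mm,
the linear equivalent of 4432 px/mm²); height-map coordinates are micrometres
(`x_um = col * pitch`, default pitch 0.5 μm/px, vertical quantum 0.01 μm).
Orientations are degrees counterclockwise from +x folded into [0, 180), since
damage features are undirected.

## Global segmentation

The detection pipeline separates the two classes by breadth:

1. **Canny edges** (σ = 2 px) flag every grayscale discontinuity against the
   bright undamaged background. Hysteresis thresholds default to the 99th
   percentile of the Gaussian gradient magnitude (low = 0.4 × high), standing
   in for the analyst-set value, with an absolute floor of 0.05 so that
   sensor noise on an undamaged surface — whose gradients sit far below real
   damage contrast — is never flagged. Both thresholds are overridable.
2. **Median suppression** (square window, default 20 × 20 px) erases linear
   features narrower than about half the window while leaving broad regions
   intact; window size is the analyst's scratch/scrape discriminator.
3. **Scrape segmentation** thresholds the filtered image (default 0.82 × the
   background median), labels connected components, drops speckle below
   0.05 mm², and polygonizes each component boundary (marching squares,
   simplified at half-pixel tolerance).
4. **Scratch mask**: the scrape regions — dilated by 5 px so the scrape
   outline's own edges are not misread as scratches — are removed from the
   *pre-median-filter* edge map. Every damage pixel therefore belongs to
   exactly one class.
5. **Hough discretization**: the scratch mask is first condensed to 1-px
   centerlines (morphological closing with a 3-px disk fills the sliver
   between the double edges that Canny produces on a thin dark line, then
   skeletonization). Skeleton junctions (points with more than two branches,
   where scratches cross) are blanked with a 2-px clearance so the line
   search cannot fit spurious chords bridging two different tracks. A
   probabilistic Hough transform (θ resolution 1°, minimum length 0.3 mm,
   gap 3 px) then extracts straight segments; curvilinear scratches come
   back as concatenations of segments.

Post-processing merges near-duplicates (orientation within 3°, widened up to
6° for short fragments whose angles are intrinsically noisy, perpendicular
offset under 6 px, axial overlap) by union-find, replacing each group with
the segment spanning the extreme projections onto the group's length-weighted
mean direction. The 6-px offset tolerance is deliberately larger than the
Canny double-edge spacing (line width plus smoothing, ≈4–6 px) so the two
edges of one scratch always unify; a 2-px tolerance leaves duplicates. A
final pass drops any short segment ≥80% of whose sampled points lie inside
the 6-px corridor of a longer kept segment (residual junction spurs and
re-detections). Segments crossing a scrape are truncated at the polygon
boundary, the scrape keeping the contested pixels.

## Registration

Global image and OP scan are aligned through analyst-picked control points —
pairs of coordinates of damage features recognizable in both. A bivariate
polynomial warp of degree 2 (six coefficients per axis, monomials ordered
[1, x, y, x², xy, y²] for serialization stability) is fit per axis by least
squares; six point pairs determine it exactly (residual ~0), more are
supported in the least-squares sense. Rank-deficient configurations (e.g.
collinear points) raise a dedicated error rather than silently extrapolating.
The degree-2 warp subsumes translation and rotation and additionally absorbs
the mild perspective/curvature distortion between a photograph of a sphere
and a tangent-plane scan, which a rigid transform cannot.

## Profilometry metrology

**Form removal.** The nominal surface is spherical; over a ≤5 mm patch its
sag is captured to < 0.02 μm by the full bivariate quadric
z = a + bx + cy + dx² + exy + fy², fit by least squares on valid pixels
(coordinates centered and scaled for conditioning) and subtracted. The full
quadric rather than a constrained sphere is used because it additionally
absorbs tilt and astigmatic mounting error; it is idempotent to 1e-9 μm.
Dropout pixels are excluded via the validity mask, never inpainted.

**Roughness.** Over a region (polygon or full map), heights are referenced
to the regional mean: Ra = mean |z − z̄| (areal average roughness),
Rp = max(z − z̄), Rv = |min(z − z̄)|. These are translation-invariant by
construction.

**Scratch lip height.** The form-removed scan is sampled along equally
spaced lines perpendicular to the segment (default spacing 10 μm, half-width
25 μm, 51 bilinear samples per line). The per-line peak is the transect
maximum — after form removal the groove contributes only negative values, so
the peak sits on a lip — and h_L is the mean of peaks. Lines clipped by the
scan border are dropped; fewer than 3 valid lines is an error. A convergence
table (`convergence_study`) reports h_L across a descending spacing ladder
and flags the coarsest spacing within 1% of the finest; the 10 μm default
passes that flag on all shipped phantoms, and halving it changes h_L by
< 1% on smooth lips.

**Microscratch direction.** The form-removed scrape scan is binarized on
Sobel gradient magnitude at its 90th percentile and searched with the classic
(accumulator) Hough transform at 0.5° resolution. The longest line — the
strongest accumulator peak, ties broken by count then smaller angle — gives
the scraping direction. If no peak reaches 0.5 × the shorter map dimension,
the texture is declared isotropic (`IsotropicTextureError`) and callers fall
back to the macro axis. On phantoms, grooved textures peak at ≥0.60 × min-dim
and isotropic ones at ≤0.43, so the 0.5 cut separates the regimes with margin
on both sides.

## Severity encoding

Empirical pin-on-plate relations convert severity to the multiplicative
elevation k_inc of the Archard wear coefficient:

- scratches: k_inc = 58.0985 · (1 − e^(−0.2237·h_L)), saturating at 58.0985
  (within 1% of the bound for h_L ≥ 20.6 μm);
- scrapes: k_inc = 37.538 · Ra^1.2.

Lips below the ~1 μm wear-consequential threshold may be Boolean-masked away
before simulation (`mask_inconsequential`); raw per-feature values are always
reported. Rasterization paints each feature's k_inc onto a grid cell-wise
(scratch: segment line dilated to its measured width, minimum one cell;
scrape: polygon fill) composing overlaps by **max**, not sum — overlapping
features should not double-count — and clamping sub-unity raw values to 1,
since an "elevation" field must never predict less wear than the undamaged
baseline. Per-cell provenance (feature id, class, direction) is retained.

Directionality is measured, stored and carried into the field's provenance,
but does not modulate k_inc: no functional form for the scratch-angle
dependence of the wear factor is established for this encoding. A pluggable
`direction_modulation` hook (default identity) marks the seam where such a
law would plug in.

## Wear integration

Per step, Δd = k0 · k_inc · p · s (k0 default 1e-6 mm per MPa·mm,
config-overridable; no baseline coefficient is canonical). Accumulation is
quasi-static — prescribed pressure/sliding fields, no geometry update — so
depth after N identical cycles is exactly N × one cycle, and the per-cell
damaged/baseline depth ratio equals the cell's k_inc wherever the baseline
wears. That identity is the point: the simulator's purpose is to quantify
what the *encoding* implies for wear acceleration, not to replace finite
element contact mechanics (explicitly out of scope, as are cross-shear wear
laws and creep). Fold increase is the damaged/baseline wear-volume ratio;
the excess volume is attributed to scratch vs scrape cells via provenance.
`hertz_patch` supplies demo kinematics: a hemispherical pressure patch
translated along a path, each step contributing its length as sliding.

## Phantom generator

Phantoms embed known damage on a spherical cap (default radius 14 mm, a
28 mm head) and drive every validation:

- **Global image**: bright background (0.90), scratches at 0.3 × background
  drawn ≥2 px wide, scrapes at 0.6 × background with mild speckle, Gaussian
  sensor noise (σ = 0.01). No published grayscale contrast exists for the
  diffused-light technique; these values are chosen so the two classes are
  separable by the default thresholds with realistic margins, and scrape
  pixels win where features overlap (mirroring the downstream rule).
- **Height map**: scratch relief is a negative Gaussian groove (σ = width/4)
  with two positive Gaussian lips (σ = max(width/6, 2 μm)) centered at the
  groove edges; the lip amplitude is solved by bisection so the profile's
  true maximum equals the requested h_L, and by default the groove depth is
  set so displaced groove volume equals lip volume (volume-conserving
  ploughing — physically motivated, and it keeps the quadric form fit
  unbiased by the scratch's net material). Scrape texture is Gaussian-
  smoothed white noise (σ = 3 px), optionally plus a quasi-periodic parallel
  groove set (24 μm period) along the stated microscratch direction, the
  whole patch rescaled to hit the target Ra exactly (realized Ra within 2%
  after quantization across targets 0.05–4.2 μm). Heights are quantized to
  the 0.01 μm instrument resolution. Same truth + seed ⇒ bit-identical
  rasters.

No measured scratch cross-sections or scrape height spectra are published
for this instrument class, so the Gaussian profile and noise spectrum are
explicit stand-ins. Consequently the validation suite demonstrates that the
*algorithms* recover known severities and directions through the full chain
(detection → registration → metrology → encoding → wear); it does not
certify performance on real interferometry artifacts such as specular
dropouts, stitching seams, or batting from surface films — those enter only
through the validity mask.

## Validated accuracy (phantom suite)

The test suite pins, among others: detection orientation MAE ≤ 2° and scrape
IoU ≥ 0.8 over 20 randomized phantoms; lip-height recovery within 0.1 μm and
Ra within 5% over 20 phantoms; form-removal residual < 0.02 μm on an exact
sphere; exact interpolation (residual < 1e-9 px) for six control points at
degree 2; areal Ra of unit Gaussian noise = √(2/π) within 0.01 (half-normal
mean); and the exact per-cell wear-ratio identity. Problem sizes were chosen
at desk scale: 5 × 5 mm global views at 40 px/mm for detection studies,
1 × 1 mm scans at 1–2 μm pitch for metrology, 10⁶-cycle wear runs on
40 × 40 grids.

## Known limitations

- Multi-view stitching of the 30° circumferential photo series into one
  spherical atlas is out of scope; features are reported per view, and
  overlapping sectors are not deduplicated (users should supply disjoint
  sector masks).
- Curvilinear scratches are concatenations of straight segments; lip height
  is averaged per segment, not per track.
- The detected endpoints of a segment are eroded by a few pixels relative to
  truth (closing/skeletonization), so detected lengths are slight
  underestimates; orientations are unaffected.
- The wear integrator is quasi-static and single-cycle-periodic; it cannot
  capture geometry evolution, creep, or cross-shear effects.
- Sub-unity raw k_inc values (very shallow lips) are clamped to 1 in the
  field; if a damage mechanism that *polishes* (reduces wear) is of
  interest, use the raw per-feature values instead.
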