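"""End-to-end pipeline: phantom -> detect -> register -> measure -> encode ->
wear -> report.

The pipeline is deterministic given a config (which embeds the phantom seed):
rerunning with the same config reproduces byte-identical CSV/JSON outputs.
Each stage logs its analyst-set parameters so every threshold used is
recorded next to the results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .encoding import (
    GridSpec,
    KincField,
    WearParams,
    kinc_scratch,
    kinc_scrape,
    mask_inconsequential,
    rasterize_kinc,
)
from .phantom import (
    DamageTruth,
    ScratchTruth,
    ScrapeTruth,
    gen_global_phantom,
    gen_heightmap_phantom,
)
from .profilometry import (
    IsotropicTextureError,
    microscratch_direction,
    remove_form,
    roughness_params,
    scratch_lip_height,
)
from .registration import ControlPointSet, apply_transform, fit_poly_transform
from .segmentation import DetectConfig, detect_damage
from .types import GlobalImage, HeightMap, ScratchSegment, ScrapeRegion
from .wear import hertz_patch, run_cycles, wear_fold_increase

log = logging.getLogger("wearmap")


@dataclass
class PipelineConfig:
    """All stage parameters for one end-to-end run.

    Round-trips losslessly through JSON/YAML; defaults match the individual
    module defaults.
    """

    # phantom
    seed: int = 0
    extent_mm: tuple[float, float] = (2.0, 2.0)
    image_scale_px_per_mm: float = 66.6  # ~4432 px/mm^2 linear equivalent
    image_noise_sd: float = 0.01
    heightmap_pitch_um: float = 2.0
    sphere_radius_mm: float = 14.0
    scratches: list[dict] = field(default_factory=list)
    scrapes: list[dict] = field(default_factory=list)
    # detection
    detect: dict = field(default_factory=dict)
    # metrology
    lip_spacing_um: float = 10.0
    lip_half_width_um: float = 25.0
    # encoding
    lip_threshold_um: float = 1.0
    wear_cell_mm: float = 0.05
    wear_params: dict = field(default_factory=dict)
    # wear demo kinematics
    peak_pressure_mpa: float = 5.0
    patch_radius_mm: float = 0.5
    n_cycles: int = 1_000_000

    def truth(self) -> DamageTruth:
        return DamageTruth(
            scratches=[ScratchTruth(**{**s, "p0": tuple(s["p0"]), "p1": tuple(s["p1"])}) for s in self.scratches],
            scrapes=[ScrapeTruth(**{**s, "polygon": [tuple(v) for v in s["polygon"]]}) for s in self.scrapes],
            sphere_radius_mm=self.sphere_radius_mm,
            seed=self.seed,
        )

    def detect_config(self) -> DetectConfig:
        return DetectConfig(**self.detect, seed=self.seed)

    def wear_parameters(self) -> WearParams:
        return WearParams(**self.wear_params, lip_threshold=self.lip_threshold_um)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        # normalize through JSON so tuples/lists compare equal after reload
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "extent_mm" in d:
            d["extent_mm"] = tuple(d["extent_mm"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls.from_dict(d)


def synth_control_points(
    img: GlobalImage, hm: HeightMap, n: int = 6, seed: int = 0
) -> ControlPointSet:
    """Stand-in for analyst-picked landmarks on a phantom pair.

    The phantom's global image and height map share a physical mm frame, so
    the true mapping from global pixels to scan micrometres is known; six
    generic (non-collinear) points are pushed through it to play the role of
    the analyst's correspondences.
    """
    rng = np.random.default_rng(seed)
    w_mm, h_mm = img.extent_mm()
    pts_mm = np.column_stack(
        [
            rng.uniform(0.1 * w_mm, 0.9 * w_mm, size=n),
            rng.uniform(0.1 * h_mm, 0.9 * h_mm, size=n),
        ]
    )
    global_px = pts_mm * img.scale
    scan_um = pts_mm * 1000.0
    return ControlPointSet(global_pts=global_px, scan_pts=scan_um)


def measure_features(
    hm_flat: HeightMap,
    segments: list[ScratchSegment],
    scrapes: list[ScrapeRegion],
    transform_mm_to_um,
    spacing_um: float = 10.0,
    half_width_um: float = 25.0,
) -> None:
    """Populate lip heights, Ra values, and microscratch directions in place.

    ``transform_mm_to_um`` maps global-frame mm coordinates into the scan's
    um frame (typically a fitted control-point polynomial composed with the
    pixel calibrations).  Features whose sampling support leaves the scan are
    left unmeasured (severity ``None``).
    """
    for seg in segments:
        pts = transform_mm_to_um(np.array([seg.p0, seg.p1]))
        scan_seg = ScratchSegment(p0=tuple(pts[0]), p1=tuple(pts[1]), feature_id=seg.feature_id)
        try:
            h_L, peaks = scratch_lip_height(
                hm_flat, scan_seg, spacing=spacing_um, half_width=half_width_um
            )
        except ValueError:
            log.warning("segment %d outside scan support; unmeasured", seg.feature_id)
            continue
        # sub-resolution negative means are metrology noise on a lip-free
        # track; lip height is physically >= 0
        seg.lip_height = max(h_L, 0.0)
        seg.peak_samples = peaks

    for sc in scrapes:
        verts = transform_mm_to_um(np.array(sc.polygon))
        try:
            summary = roughness_params(hm_flat, [tuple(v) for v in verts])
        except ValueError:
            log.warning("scrape %d outside scan support; unmeasured", sc.feature_id)
            continue
        sc.Ra = summary.Ra
        # microscratch direction from the scrape's bounding box crop
        xs, ys = verts[:, 0] / hm_flat.pitch, verts[:, 1] / hm_flat.pitch
        r0, r1 = max(int(ys.min()), 0), min(int(math.ceil(ys.max())), hm_flat.shape[0])
        c0, c1 = max(int(xs.min()), 0), min(int(math.ceil(xs.max())), hm_flat.shape[1])
        if r1 - r0 < 8 or c1 - c0 < 8:
            continue
        crop = HeightMap(
            z=hm_flat.z[r0:r1, c0:c1],
            pitch=hm_flat.pitch,
            valid_mask=hm_flat.valid_mask[r0:r1, c0:c1],
        )
        try:
            sc.micro_direction = microscratch_direction(crop)
        except IsotropicTextureError:
            log.info("scrape %d texture isotropic; macro direction kept", sc.feature_id)
            sc.micro_direction = None


def summarize_features(
    segments: list[ScratchSegment], scrapes: list[ScrapeRegion]
) -> pd.DataFrame:
    """Per-class severity summary: count, mean, SD, min, max (plus mean
    segment length / scrape area).

    SD is the sample standard deviation (n-1 denominator); for a single
    feature it is reported as 0 with ``sd_flag='single-feature'``.  Classes
    with no measured features are omitted.
    """
    rows = []
    lips = [s.lip_height for s in segments if s.lip_height is not None]
    if lips:
        rows.append(
            {
                "class": "scratch",
                "count": len(lips),
                "mean_severity_um": float(np.mean(lips)),
                "sd_severity_um": float(np.std(lips, ddof=1)) if len(lips) > 1 else 0.0,
                "min_severity_um": float(np.min(lips)),
                "max_severity_um": float(np.max(lips)),
                "mean_size": float(np.mean([s.length for s in segments if s.lip_height is not None])),
                "size_units": "mm (segment length)",
                "sd_flag": "" if len(lips) > 1 else "single-feature",
            }
        )
    ras = [s.Ra for s in scrapes if s.Ra is not None]
    if ras:
        rows.append(
            {
                "class": "scrape",
                "count": len(ras),
                "mean_severity_um": float(np.mean(ras)),
                "sd_severity_um": float(np.std(ras, ddof=1)) if len(ras) > 1 else 0.0,
                "min_severity_um": float(np.min(ras)),
                "max_severity_um": float(np.max(ras)),
                "mean_size": float(np.mean([s.area for s in scrapes if s.Ra is not None])),
                "size_units": "mm^2 (scrape area)",
                "sd_flag": "" if len(ras) > 1 else "single-feature",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    segments: list[ScratchSegment]
    scrapes: list[ScrapeRegion]
    retained_segments: list[ScratchSegment]
    features: pd.DataFrame
    summary: pd.DataFrame
    kinc: KincField
    fold_increase: float
    scratch_fraction: float
    scrape_fraction: float


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full phantom-driven pipeline and (optionally) write the
    report bundle to ``out_dir``."""
    truth = config.truth()
    log.info("stage=phantom seed=%d extent=%s", config.seed, config.extent_mm)
    img, _masks = gen_global_phantom(
        truth,
        extent_mm=config.extent_mm,
        scale=config.image_scale_px_per_mm,
        noise_sd=config.image_noise_sd,
    )
    hm, _ = gen_heightmap_phantom(
        truth, pitch=config.heightmap_pitch_um, extent_mm=config.extent_mm
    )

    log.info("stage=detect %s", config.detect or "(defaults)")
    segments, scrapes = detect_damage(img, config.detect_config())

    log.info("stage=register control_points=6 degree=2")
    cps = synth_control_points(img, hm, seed=config.seed)
    T = fit_poly_transform(cps, degree=2)

    def mm_to_um(pts_mm: np.ndarray) -> np.ndarray:
        return apply_transform(T, np.asarray(pts_mm) * config.image_scale_px_per_mm)

    log.info(
        "stage=measure spacing=%g um half_width=%g um",
        config.lip_spacing_um,
        config.lip_half_width_um,
    )
    hm_flat = remove_form(hm)
    measure_features(
        hm_flat,
        segments,
        scrapes,
        mm_to_um,
        spacing_um=config.lip_spacing_um,
        half_width_um=config.lip_half_width_um,
    )

    params = config.wear_parameters()
    measured = [s for s in segments if s.lip_height is not None]
    retained = mask_inconsequential(measured, threshold=config.lip_threshold_um)
    masked_ids = {s.feature_id for s in measured} - {s.feature_id for s in retained}
    log.info(
        "stage=encode threshold=%g um: %d detected, %d retained",
        config.lip_threshold_um,
        len(segments),
        len(retained),
    )

    w_mm, h_mm = img.extent_mm()
    spec = GridSpec(
        shape=(int(round(h_mm / config.wear_cell_mm)), int(round(w_mm / config.wear_cell_mm))),
        cell_size_mm=config.wear_cell_mm,
    )
    measured_scrapes = [s for s in scrapes if s.Ra is not None]
    kinc = rasterize_kinc(retained, measured_scrapes, spec, params)

    log.info("stage=wear cycles=%d", config.n_cycles)
    # sweep the contact patch along the diagonal in fine steps so every
    # damaged cell on the track is overpassed
    n_path = 25
    path = [
        (0.1 * w_mm + t * 0.8 * w_mm, 0.1 * h_mm + t * 0.8 * h_mm)
        for t in np.linspace(0.0, 1.0, n_path)
    ]
    cycle = hertz_patch(
        spec.shape,
        config.wear_cell_mm,
        config.peak_pressure_mpa,
        config.patch_radius_mm,
        path,
    )
    damaged = run_cycles(kinc, cycle, config.n_cycles, params)
    baseline_field = KincField(
        grid=np.ones(spec.shape),
        spec=spec,
        provenance=np.full(spec.shape, -1, dtype=int),
        cell_class=np.zeros(spec.shape, dtype=np.uint8),
        direction_deg=np.full(spec.shape, np.nan),
    )
    baseline = run_cycles(baseline_field, cycle, config.n_cycles, params)
    fold = wear_fold_increase(damaged, baseline, kinc)

    kmap = {("scratch", s.feature_id): kinc_scratch(s.lip_height, params) for s in measured}
    kmap.update({("scrape", s.feature_id): kinc_scrape(s.Ra, params) for s in measured_scrapes})
    features = wio.features_to_dataframe(segments, scrapes, kmap, masked_ids)
    summary = summarize_features(segments, scrapes)

    result = PipelineResult(
        segments=segments,
        scrapes=scrapes,
        retained_segments=retained,
        features=features,
        summary=summary,
        kinc=kinc,
        fold_increase=fold.fold,
        scratch_fraction=fold.scratch_fraction,
        scrape_fraction=fold.scrape_fraction,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.json")
        wio.save_global_image(img, out / "global_image.png")
        wio.save_heightmap(hm, out / "heightmap.tif")
        wio.save_features(features, out / "features.csv", out / "features.json")
        summary.to_csv(out / "summary.csv", index=False, float_format=wio.FLOAT_FMT)
        wio.save_kinc_field(kinc, out / "kinc.tif", out / "kinc.json")
        wio.save_wear_result(damaged, out / "wear_depth.tif", out / "wear_summary.json")
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "n_scratches_detected": len(segments),
                    "n_scratches_retained": len(retained),
                    "n_scrapes": len(scrapes),
                    "fold_increase": float(f"{fold.fold:.6g}"),
                    "scratch_fraction": float(f"{fold.scratch_fraction:.6g}"),
                    "scrape_fraction": float(f"{fold.scrape_fraction:.6g}"),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
    return result
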