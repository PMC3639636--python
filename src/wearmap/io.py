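"""File formats: images, height maps, feature tables, fields.

Global images are 8-bit grayscale PNG/TIFF; height maps are 32-bit float
TIFF (um) or CSV matrices; feature tables are CSV with WKT geometry plus a
JSON mirror; gridded fields are 32-bit float TIFF with JSON metadata.
All floating-point table output is written at 6 significant figures so reruns
diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString

from .encoding import GridSpec, KincField
from .types import GlobalImage, HeightMap, ScratchSegment, ScrapeRegion
from .wear import WearResult

FEATURE_SCHEMA_VERSION = "1"
FEATURE_COLUMNS = [
    "feature_id",
    "class",
    "geometry_wkt",
    "orientation_deg",
    "micro_direction_deg",
    "severity_um",
    "kinc",
    "masked",
]

FLOAT_FMT = "%.6g"


def load_global_image(path, scale: float, view_id: str | None = None) -> GlobalImage:
    """Read an 8-bit grayscale PNG/TIFF as a calibrated global image."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return GlobalImage(pixels=arr, scale=scale, view_id=view_id or Path(path).stem)


def save_global_image(img: GlobalImage, path) -> None:
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_heightmap(path, pitch: float = 0.5) -> HeightMap:
    """Read a height map: float TIFF (um) or CSV matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        z = tifffile.imread(path).astype(float)
    else:
        z = np.loadtxt(path, delimiter=",", ndmin=2)
    valid = np.isfinite(z)
    z = np.where(valid, z, 0.0)
    return HeightMap(z=z, pitch=pitch, valid_mask=valid)


def save_heightmap(hm: HeightMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        z = np.where(hm.valid_mask, hm.z, np.nan).astype(np.float32)
        tifffile.imwrite(path, z)
    else:
        np.savetxt(path, hm.z, delimiter=",", fmt=FLOAT_FMT)


def _row_for_scratch(s: ScratchSegment, kinc: float | None, masked: bool) -> dict:
    return {
        "feature_id": s.feature_id,
        "class": "scratch",
        "geometry_wkt": LineString([s.p0, s.p1]).wkt,
        "orientation_deg": s.orientation,
        "micro_direction_deg": np.nan,
        "severity_um": np.nan if s.lip_height is None else s.lip_height,
        "kinc": np.nan if kinc is None else kinc,
        "masked": masked,
    }


def _row_for_scrape(s: ScrapeRegion, kinc: float | None) -> dict:
    return {
        "feature_id": s.feature_id,
        "class": "scrape",
        "geometry_wkt": s.shapely.wkt,
        "orientation_deg": s.macro_direction,
        "micro_direction_deg": np.nan if s.micro_direction is None else s.micro_direction,
        "severity_um": np.nan if s.Ra is None else s.Ra,
        "kinc": np.nan if kinc is None else kinc,
        "masked": False,
    }


def features_to_dataframe(
    segments: list[ScratchSegment],
    scrapes: list[ScrapeRegion],
    kinc_by_feature: dict[tuple[str, int], float] | None = None,
    masked_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Assemble the canonical feature table (schema v1)."""
    kmap = kinc_by_feature or {}
    masked = masked_ids or set()
    rows = [
        _row_for_scratch(s, kmap.get(("scratch", s.feature_id)), s.feature_id in masked)
        for s in segments
    ]
    rows += [_row_for_scrape(s, kmap.get(("scrape", s.feature_id))) for s in scrapes]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["schema_version"] = FEATURE_SCHEMA_VERSION
    return df


def save_features(df: pd.DataFrame, csv_path, json_path=None) -> None:
    df = df.copy()
    df.insert(0, "schema", FEATURE_SCHEMA_VERSION)
    df.to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    if json_path is not None:
        records = json.loads(df.to_json(orient="records"))
        with open(json_path, "w") as fh:
            json.dump({"schema": FEATURE_SCHEMA_VERSION, "features": records}, fh, indent=2)


def load_features(csv_path) -> tuple[list[ScratchSegment], list[ScrapeRegion]]:
    """Reconstruct feature objects from a feature-table CSV."""
    df = pd.read_csv(csv_path)
    segments, scrapes = [], []
    for _, row in df.iterrows():
        geom = shapely_wkt.loads(row["geometry_wkt"])
        if row["class"] == "scratch":
            coords = list(geom.coords)
            seg = ScratchSegment(p0=tuple(coords[0]), p1=tuple(coords[-1]))
            seg.feature_id = int(row["feature_id"])
            if np.isfinite(row["severity_um"]):
                seg.lip_height = float(row["severity_um"])
            segments.append(seg)
        else:
            sc = ScrapeRegion(polygon=list(geom.exterior.coords))
            sc.feature_id = int(row["feature_id"])
            if np.isfinite(row["severity_um"]):
                sc.Ra = float(row["severity_um"])
            if np.isfinite(row["micro_direction_deg"]):
                sc.micro_direction = float(row["micro_direction_deg"])
            scrapes.append(sc)
    return segments, scrapes


def save_kinc_field(field: KincField, tiff_path, meta_path) -> None:
    tifffile.imwrite(tiff_path, field.grid.astype(np.float32))
    meta = {
        "shape": list(field.spec.shape),
        "cell_size_mm": field.spec.cell_size_mm,
        "origin_mm": list(field.spec.origin_mm),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_kinc_field(tiff_path, meta_path) -> KincField:
    grid = tifffile.imread(tiff_path).astype(float)
    with open(meta_path) as fh:
        meta = json.load(fh)
    spec = GridSpec(
        shape=tuple(meta["shape"]),
        cell_size_mm=meta["cell_size_mm"],
        origin_mm=tuple(meta["origin_mm"]),
    )
    return KincField(
        grid=grid,
        spec=spec,
        provenance=np.full(grid.shape, -1, dtype=int),
        cell_class=np.zeros(grid.shape, dtype=np.uint8),
        direction_deg=np.full(grid.shape, np.nan),
    )


def save_wear_result(result: WearResult, tiff_path, summary_path) -> None:
    tifffile.imwrite(tiff_path, result.depth.astype(np.float32))
    summary = {
        "volume_mm3": float(f"{result.volume:.6g}"),
        "max_depth_um": float(f"{result.depth.max():.6g}"),
        "cycles": result.cycles,
        "cell_area_mm2": result.cell_area_mm2,
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
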