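import math

import numpy as np
import pytest

import wearmap as wm


@pytest.fixture(scope="session")
def five_mm_truth() -> wm.DamageTruth:
    """Phantom with 3 scratches + 2 scrapes on a 5 x 5 mm field."""
    return wm.DamageTruth(
        scratches=[
            wm.ScratchTruth(p0=(0.5, 4.0), p1=(2.5, 2.8)),
            wm.ScratchTruth(p0=(3.2, 0.5), p1=(3.4, 3.5)),
            wm.ScratchTruth(p0=(0.5, 0.5), p1=(2.0, 0.7)),
        ],
        scrapes=[
            wm.ScrapeTruth(
                polygon=[(0.5, 1.2), (2.5, 1.2), (2.5, 2.2), (0.5, 2.2)],
                target_ra_um=1.0,
            ),
            wm.ScrapeTruth(
                polygon=[(3.8, 3.8), (4.6, 3.8), (4.6, 4.6), (3.8, 4.6)],
                target_ra_um=0.5,
            ),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def five_mm_image(five_mm_truth):
    img, masks = wm.gen_global_phantom(five_mm_truth, extent_mm=(5.0, 5.0), scale=40.0)
    return img, masks


@pytest.fixture(scope="session")
def lip_scan():
    """Form-removed 1 x 1 mm scan of a single 2.0-um-lip scratch.

    Returns (flat_map, scan-frame segment, truth).
    """
    truth = wm.DamageTruth(
        scratches=[
            wm.ScratchTruth(p0=(0.1, 0.2), p1=(0.9, 0.8), lip_height_um=2.0)
        ],
        seed=3,
    )
    hm, _ = wm.gen_heightmap_phantom(truth, pitch=1.0, extent_mm=(1.0, 1.0))
    flat = wm.remove_form(hm)
    seg = wm.ScratchSegment(p0=(100.0, 200.0), p1=(900.0, 800.0))
    return flat, seg, truth


def random_recovery_truth(seed: int) -> wm.DamageTruth:
    """Randomized phantom used by the detection-recovery studies."""
    rng = np.random.default_rng(seed)
    scratches = []
    for _ in range(int(rng.integers(1, 4))):
        ang = rng.uniform(0, 180)
        length = rng.uniform(1.2, 2.5)
        cx, cy = rng.uniform(1.2, 3.8, 2)
        dx = length / 2 * math.cos(math.radians(ang))
        dy = length / 2 * math.sin(math.radians(ang))
        scratches.append(wm.ScratchTruth(p0=(cx - dx, cy - dy), p1=(cx + dx, cy + dy)))
    w, h = rng.uniform(0.8, 1.6), rng.uniform(0.5, 1.0)
    a = math.radians(rng.uniform(0, 180))
    cx, cy = rng.uniform(1.2, 3.8, 2)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    corners = [
        np.array([cx, cy]) + rot @ np.array(p)
        for p in [(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)]
    ]
    scrapes = [wm.ScrapeTruth(polygon=[tuple(c) for c in corners], target_ra_um=1.0)]
    return wm.DamageTruth(scratches=scratches, scrapes=scrapes, seed=int(seed))
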