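"""Detection pipeline: Canny, median suppression, scrape/scratch split, Hough."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import wearmap as wm
from wearmap.segmentation import scrape_pixel_mask, thin_scratch_mask


def _blank(scale=40.0, extent=(2.0, 2.0), value=0.9):
    h = int(extent[1] * scale)
    w = int(extent[0] * scale)
    return wm.GlobalImage(pixels=np.full((h, w), value), scale=scale)


class TestCanny:
    def test_uniform_image_has_no_edges(self):
        assert not wm.canny_damage_edges(_blank()).any()

    def test_scratch_pixels_near_flagged_edges(self, five_mm_image, five_mm_truth):
        img, masks = five_mm_image
        edges = wm.canny_damage_edges(img)
        from scipy.ndimage import distance_transform_edt

        d_to_edge = distance_transform_edt(~edges)
        for m in masks["scratch"]:
            frac = (d_to_edge[m] <= 2.0).mean()
            assert frac >= 0.9

    def test_threshold_above_max_gradient_empties_result(self, five_mm_image):
        img, _ = five_mm_image
        edges = wm.canny_damage_edges(img, low=10.0, high=20.0)
        assert not edges.any()

    def test_rejects_inverted_thresholds(self, five_mm_image):
        img, _ = five_mm_image
        with pytest.raises(ValueError):
            wm.canny_damage_edges(img, low=0.5, high=0.1)


class TestMedianSuppress:
    def test_thin_line_blurred_away(self):
        img = _blank(extent=(3.0, 3.0))
        img.pixels[60, 20:100] = 0.27  # 1-px line; breadth << size/2
        img.pixels[59, 20:100] = 0.27
        img.pixels[61, 20:100] = 0.27
        out = wm.median_suppress(img, size=20)
        assert abs(out.pixels[59:62, 30:90].mean() - 0.9) < 0.01

    def test_broad_patch_survives(self):
        img = _blank(extent=(3.0, 3.0))
        img.pixels[30:90, 30:90] = 0.54  # 60-px patch vs 20-px filter
        out = wm.median_suppress(img, size=20)
        inner = out.pixels[45:75, 45:75]
        assert abs(inner.mean() - 0.54) / 0.54 < 0.05

    def test_size_one_is_identity(self):
        img, _ = wm.gen_global_phantom(wm.DamageTruth(seed=3), extent_mm=(1.0, 1.0), scale=40.0)
        out = wm.median_suppress(img, size=1)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_rejects_noninteger_size(self):
        with pytest.raises(ValueError):
            wm.median_suppress(_blank(), size=0)


class TestSegmentScrapes:
    def test_phantom_scrape_polygon_area_and_iou(self):
        truth = wm.DamageTruth(
            scrapes=[wm.ScrapeTruth(polygon=[(1.0, 1.0), (3.0, 1.0), (3.0, 3.0), (1.0, 3.0)])],
            seed=4,
        )
        img, _ = wm.gen_global_phantom(truth, extent_mm=(4.0, 4.0), scale=40.0)
        filtered = wm.median_suppress(img, size=20)
        regions = wm.segment_scrapes(filtered)
        assert len(regions) == 1
        assert regions[0].area == pytest.approx(4.0, rel=0.10)
        tp = Polygon(truth.scrapes[0].polygon)
        iou = regions[0].shapely.intersection(tp).area / regions[0].shapely.union(tp).area
        assert iou >= 0.85

    def test_blank_image_yields_no_scrapes(self):
        assert wm.segment_scrapes(_blank()) == []

    def test_two_disjoint_patches_give_two_polygons(self):
        truth = wm.DamageTruth(
            scrapes=[
                wm.ScrapeTruth(polygon=[(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)]),
                wm.ScrapeTruth(polygon=[(2.5, 2.5), (3.5, 2.5), (3.5, 3.5), (2.5, 3.5)]),
            ],
            seed=4,
        )
        img, _ = wm.gen_global_phantom(truth, extent_mm=(4.0, 4.0), scale=40.0)
        regions = wm.segment_scrapes(wm.median_suppress(img, size=20))
        assert len(regions) == 2


class TestScratchMask:
    def test_edges_inside_scrape_cleared(self):
        edges = np.zeros((100, 100), bool)
        edges[40:60, 40:60] = True
        scrape = wm.ScrapeRegion(polygon=[(0.5, 0.5), (2.0, 0.5), (2.0, 2.0), (0.5, 2.0)])
        out = wm.scratch_mask(edges, [scrape], scale=40.0)
        assert not out.any()

    def test_no_scrapes_is_identity(self):
        edges = np.random.default_rng(0).random((50, 50)) > 0.9
        out = wm.scratch_mask(edges, [], scale=40.0)
        np.testing.assert_array_equal(out, edges)

    def test_scratch_outside_scrape_unchanged(self):
        edges = np.zeros((100, 100), bool)
        edges[10, 5:95] = True
        scrape = wm.ScrapeRegion(polygon=[(0.5, 1.0), (2.0, 1.0), (2.0, 2.0), (0.5, 2.0)])
        out = wm.scratch_mask(edges, [scrape], scale=40.0)
        np.testing.assert_array_equal(out, edges)


class TestHoughSegments:
    def test_single_line_orientation_and_length(self):
        mask = np.zeros((200, 200), bool)
        # 2-mm line at 30 deg, scale 40 px/mm -> 80 px long
        x0, y0 = 40.0, 40.0
        for t in np.linspace(0, 1, 300):
            x = x0 + t * 80 * math.cos(math.radians(30))
            y = y0 + t * 80 * math.sin(math.radians(30))
            mask[int(round(y)), int(round(x))] = True
        segs = wm.hough_scratch_segments(mask, scale=40.0)
        assert len(segs) == 1
        assert segs[0].orientation == pytest.approx(30.0, abs=2.0)
        assert segs[0].length == pytest.approx(2.0, abs=0.1)

    def test_blank_mask_gives_no_segments(self):
        assert wm.hough_scratch_segments(np.zeros((50, 50), bool), scale=40.0) == []

    def test_arc_discretized_into_multiple_segments(self):
        # arc of radius 5 mm spanning 60 deg of tangent range at 40 px/mm
        mask = np.zeros((250, 250), bool)
        R = 200.0
        angles = np.linspace(math.radians(195), math.radians(255), 1200)
        cx, cy = 230.0, 230.0
        for a in angles:
            x, y = cx + R * math.cos(a), cy + R * math.sin(a)
            if 0 <= int(y) < 250 and 0 <= int(x) < 250:
                mask[int(round(y)), int(round(x))] = True
        segs = wm.hough_scratch_segments(mask, scale=40.0)
        assert len(segs) >= 2
        arc_len_mm = R / 40.0 * math.radians(60)
        total = sum(s.length for s in segs)
        assert total >= 0.8 * arc_len_mm
        orientations = [s.orientation for s in segs]
        assert max(orientations) - min(orientations) >= 25.0

    def test_rejects_nonpositive_min_length(self):
        with pytest.raises(ValueError):
            wm.hough_scratch_segments(np.ones((10, 10), bool), scale=40.0, min_length_mm=0.0)


class TestDetectDamage:
    def test_counts_on_mixed_phantom(self, five_mm_image):
        img, _ = five_mm_image
        segments, scrapes = wm.detect_damage(img)
        assert len(segments) == 3
        assert len(scrapes) == 2

    def test_blank_image_detects_nothing(self):
        segments, scrapes = wm.detect_damage(_blank(extent=(3.0, 3.0)))
        assert segments == [] and scrapes == []

    def test_scratch_crossing_scrape_is_truncated(self):
        truth = wm.DamageTruth(
            scratches=[wm.ScratchTruth(p0=(0.3, 2.0), p1=(3.7, 2.1))],
            scrapes=[wm.ScrapeTruth(polygon=[(1.5, 1.2), (2.5, 1.2), (2.5, 2.8), (1.5, 2.8)])],
            seed=8,
        )
        img, _ = wm.gen_global_phantom(truth, extent_mm=(4.0, 4.0), scale=40.0)
        segments, scrapes = wm.detect_damage(img)
        assert len(scrapes) == 1
        assert len(segments) >= 1
        # no segment may reach deeper than a small tolerance into the scrape
        from shapely.geometry import LineString

        core = scrapes[0].shapely.buffer(-0.05)
        for seg in segments:
            assert not core.intersects(LineString([seg.p0, seg.p1]))

    def test_classification_dichotomy(self, five_mm_image):
        """Every detected damage pixel is scratch or scrape, never both."""
        img, _ = five_mm_image
        edges = wm.canny_damage_edges(img)
        filtered = wm.median_suppress(img)
        scrapes = wm.segment_scrapes(filtered)
        smask = wm.scratch_mask(edges, scrapes, img.scale)
        region = scrape_pixel_mask(edges.shape, scrapes, img.scale)
        # scratch mask and scrape region partition the edge pixels
        assert not (smask & region).any()
        assert (smask ^ (edges & region)).sum() == edges.sum()

    def test_median_monotonicity_scrape_never_becomes_scratch(self, five_mm_image):
        """Growing the median size only shrinks what survives filtering."""
        img, _ = five_mm_image
        survivors = []
        for size in (10, 20, 40):
            filtered = wm.median_suppress(img, size=size)
            dark = filtered.pixels < 0.7
            survivors.append(dark.sum())
        assert survivors[0] >= survivors[1] >= survivors[2]


class TestThinning:
    def test_double_edge_pair_collapses_to_single_track(self):
        mask = np.zeros((60, 200), bool)
        mask[28, 10:190] = True
        mask[33, 10:190] = True  # parallel Canny pair, 5 px apart
        thin = thin_scratch_mask(mask, close_radius_px=3)
        cols = np.nonzero(thin.any(axis=0))[0]
        rows_per_col = thin[:, cols].sum(axis=0)
        assert np.median(rows_per_col) == 1.0
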