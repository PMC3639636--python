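"""Profilometry metrology: form removal, roughness, lip height, directions."""

import math

import numpy as np
import pytest

import wearmap as wm
from wearmap.phantom import sphere_cap
from wearmap.profilometry import DegenerateSurfaceError


class TestRemoveForm:
    def test_sphere_with_tilt_absorbed(self):
        shape = (400, 400)
        z = sphere_cap(shape, 1.0, 14.0)
        rr, cc = np.mgrid[0:400, 0:400]
        z = z + 0.005 * cc + 0.002 * rr + 3.0  # tilt plane + offset
        flat = wm.remove_form(wm.HeightMap(z=z, pitch=1.0))
        assert np.abs(flat.z).max() < 0.02

    def test_lip_survives_form_removal(self, lip_scan):
        flat, seg, truth = lip_scan
        h_L, _ = wm.scratch_lip_height(flat, seg)
        assert h_L == pytest.approx(truth.scratches[0].lip_height_um, abs=0.05)

    def test_idempotent(self, lip_scan):
        flat, _, _ = lip_scan
        again = wm.remove_form(flat)
        np.testing.assert_allclose(again.z, flat.z, atol=1e-9)

    def test_degenerate_support_raises(self):
        z = np.zeros((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[5, :] = True  # collinear row
        with pytest.raises(DegenerateSurfaceError):
            wm.remove_form(wm.HeightMap(z=z, pitch=1.0, valid_mask=mask))

    def test_respects_valid_mask(self):
        z = sphere_cap((200, 200), 1.0, 14.0).copy()
        mask = np.ones((200, 200), bool)
        z[50:60, 50:60] = 500.0  # dropout garbage
        mask[50:60, 50:60] = False
        flat = wm.remove_form(wm.HeightMap(z=z, pitch=1.0, valid_mask=mask))
        assert np.abs(flat.z[mask]).max() < 0.02


class TestRoughness:
    def test_constant_surface_is_zero(self):
        r = wm.roughness_params(wm.HeightMap(z=np.full((50, 50), 3.3), pitch=1.0))
        assert r.Ra == r.Rp == r.Rv == 0.0

    def test_symmetric_binary_surface(self):
        z = np.ones((10, 10))
        z[:5] = -1.0
        r = wm.roughness_params(wm.HeightMap(z=z, pitch=1.0))
        assert r.Ra == pytest.approx(1.0)
        assert r.Rp == pytest.approx(1.0)
        assert r.Rv == pytest.approx(1.0)

    def test_gaussian_noise_ra_matches_half_normal_mean(self):
        rng = np.random.default_rng(12345)
        z = rng.normal(0.0, 1.0, size=(1000, 1000))
        r = wm.roughness_params(wm.HeightMap(z=z, pitch=1.0))
        assert r.Ra == pytest.approx(math.sqrt(2.0 / math.pi), abs=0.01)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(60, 60))
        a = wm.roughness_params(wm.HeightMap(z=z, pitch=1.0))
        b = wm.roughness_params(wm.HeightMap(z=z + 17.3, pitch=1.0))
        assert a.Ra == pytest.approx(b.Ra, abs=1e-12)
        assert a.Rp == pytest.approx(b.Rp, abs=1e-12)
        assert a.Rv == pytest.approx(b.Rv, abs=1e-12)

    def test_ra_bounded_by_max_deviation(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(40, 40))
        r = wm.roughness_params(wm.HeightMap(z=z, pitch=1.0))
        assert r.Ra <= max(r.Rp, r.Rv)

    def test_empty_region_raises(self):
        hm = wm.HeightMap(z=np.zeros((10, 10)), pitch=1.0)
        with pytest.raises(ValueError):
            wm.roughness_params(hm, np.zeros((10, 10), bool))


class TestLipHeight:
    def test_flat_surface_gives_near_zero(self):
        hm = wm.HeightMap(z=np.zeros((300, 300)), pitch=1.0)
        seg = wm.ScratchSegment(p0=(50.0, 150.0), p1=(250.0, 150.0))
        h_L, _ = wm.scratch_lip_height(hm, seg)
        assert abs(h_L) < 0.02

    def test_ramping_lip_averages_to_midpoint(self):
        # lip ramping 1 -> 3 um linearly along the track: mean must be ~2
        truth_a = wm.DamageTruth(
            scratches=[wm.ScratchTruth(p0=(0.1, 0.5), p1=(0.9, 0.5), lip_height_um=1.0)],
            seed=6,
        )
        hm, _ = wm.gen_heightmap_phantom(truth_a, pitch=1.0, extent_mm=(1.0, 1.0), quantize=False)
        # superpose a second render with the ramp complement to build the ramp
        shape = hm.z.shape
        xs = np.linspace(0.0, 1.0, shape[1])
        ramp = 1.0 + 2.0 * np.clip((xs - 0.1) / 0.8, 0, 1)  # 1..3 over the track
        base = hm.z - sphere_cap(shape, 1.0, 14.0)
        scaled = base * ramp[None, :]
        flat = wm.remove_form(wm.HeightMap(z=scaled + sphere_cap(shape, 1.0, 14.0), pitch=1.0))
        seg = wm.ScratchSegment(p0=(100.0, 500.0), p1=(900.0, 500.0))
        h_L, _ = wm.scratch_lip_height(flat, seg)
        assert h_L == pytest.approx(2.0, abs=0.1)

    def test_too_few_lines_raises(self):
        hm = wm.HeightMap(z=np.zeros((40, 40)), pitch=1.0)
        seg = wm.ScratchSegment(p0=(5.0, 20.0), p1=(35.0, 20.0))
        with pytest.raises(ValueError):
            wm.scratch_lip_height(hm, seg, spacing=10.0, half_width=30.0)

    def test_rejects_nonpositive_spacing(self, lip_scan):
        flat, seg, _ = lip_scan
        with pytest.raises(ValueError):
            wm.scratch_lip_height(flat, seg, spacing=0.0)

    def test_halving_spacing_is_stable(self, lip_scan):
        flat, seg, _ = lip_scan
        a, _ = wm.scratch_lip_height(flat, seg, spacing=10.0)
        b, _ = wm.scratch_lip_height(flat, seg, spacing=5.0)
        assert abs(b - a) / a < 0.01


class TestConvergence:
    def test_uniform_lip_converges_immediately(self, lip_scan):
        flat, seg, _ = lip_scan
        table = wm.convergence_study(flat, seg, [80.0, 40.0, 20.0, 10.0])
        assert table["h_L_um"].max() - table["h_L_um"].min() < 0.02
        assert table["converged"].any()
        # the flag goes to the coarsest adequate spacing
        assert table.loc[table["converged"]].index[0] == 0

    def test_single_spacing_row_no_flag(self, lip_scan):
        flat, seg, _ = lip_scan
        table = wm.convergence_study(flat, seg, [20.0])
        assert len(table) == 1
        assert not table["converged"].any()

    def test_unsorted_spacings_rejected(self, lip_scan):
        flat, seg, _ = lip_scan
        with pytest.raises(ValueError):
            wm.convergence_study(flat, seg, [10.0, 20.0])

    def test_modulated_lip_error_shrinks_below_nyquist(self):
        """Sinusoidally modulated lip: error vs truth drops once the sampling
        spacing resolves the modulation period."""
        period_um = 200.0
        truth = wm.DamageTruth(
            scratches=[wm.ScratchTruth(p0=(0.1, 0.5), p1=(0.9, 0.5), lip_height_um=2.0)],
            seed=13,
        )
        hm, _ = wm.gen_heightmap_phantom(truth, pitch=1.0, extent_mm=(1.0, 1.0), quantize=False)
        shape = hm.z.shape
        xs = np.arange(shape[1]) * 1.0
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * xs / period_um)
        base = hm.z - sphere_cap(shape, 1.0, 14.0)
        flat = wm.remove_form(
            wm.HeightMap(z=base * mod[None, :] + sphere_cap(shape, 1.0, 14.0), pitch=1.0)
        )
        seg = wm.ScratchSegment(p0=(100.0, 500.0), p1=(900.0, 500.0))
        fine, _ = wm.scratch_lip_height(flat, seg, spacing=5.0)
        coarse, _ = wm.scratch_lip_height(flat, seg, spacing=150.0)
        mid, _ = wm.scratch_lip_height(flat, seg, spacing=40.0)
        assert abs(mid - fine) <= abs(coarse - fine) + 1e-9
        assert abs(mid - fine) / fine < 0.05


class TestMicroscratchDirection:
    @pytest.mark.parametrize("angle", [30.0, 75.0, 120.0])
    def test_groove_direction_recovered(self, angle):
        truth = wm.DamageTruth(
            scrapes=[
                wm.ScrapeTruth(
                    polygon=[(0.1, 0.1), (0.9, 0.1), (0.9, 0.9), (0.1, 0.9)],
                    target_ra_um=1.0,
                    micro_direction_deg=angle,
                )
            ],
            seed=9,
        )
        hm, _ = wm.gen_heightmap_phantom(truth, pitch=2.0, extent_mm=(1.0, 1.0))
        flat = wm.remove_form(hm)
        crop = wm.HeightMap(z=flat.z[75:425, 75:425], pitch=2.0)
        assert wm.microscratch_direction(crop) == pytest.approx(angle, abs=3.0)

    def test_isotropic_texture_flagged(self):
        for seed in range(10):
            truth = wm.DamageTruth(
                scrapes=[
                    wm.ScrapeTruth(
                        polygon=[(0.1, 0.1), (0.9, 0.1), (0.9, 0.9), (0.1, 0.9)],
                        target_ra_um=1.0,
                    )
                ],
                seed=300 + seed,
            )
            hm, _ = wm.gen_heightmap_phantom(truth, pitch=2.0, extent_mm=(1.0, 1.0))
            flat = wm.remove_form(hm)
            crop = wm.HeightMap(z=flat.z[75:425, 75:425], pitch=2.0)
            with pytest.raises(wm.IsotropicTextureError):
                wm.microscratch_direction(crop)

    def test_micro_direction_trumps_macro_axis(self):
        """Elongated scrape along x (macro 0 deg) with grooves at 60 deg:
        the reported scraping direction is the groove direction."""
        truth = wm.DamageTruth(
            scrapes=[
                wm.ScrapeTruth(
                    polygon=[(0.1, 0.35), (0.9, 0.35), (0.9, 0.65), (0.1, 0.65)],
                    target_ra_um=1.0,
                    micro_direction_deg=60.0,
                )
            ],
            seed=21,
        )
        assert truth.scrapes[0].macro_direction_deg == pytest.approx(0.0, abs=1.0)
        hm, _ = wm.gen_heightmap_phantom(truth, pitch=2.0, extent_mm=(1.0, 1.0))
        flat = wm.remove_form(hm)
        crop = wm.HeightMap(z=flat.z[185:315, 60:440], pitch=2.0)
        assert wm.microscratch_direction(crop) == pytest.approx(60.0, abs=3.0)
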