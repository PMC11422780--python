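"""Synthetic scene generator: spectral building blocks, noise model,
ground-truth consistency and the full study table."""

import numpy as np
import pytest

from samcover.angles import Spectrum, mean_spectrum, spectral_angle
from samcover.datacube import Datacube, default_grid
from samcover.roi import ROI
from samcover.synth import (
    MODEL_PRESETS,
    PRODUCT_PRESETS,
    ProductParams,
    SimConfig,
    SkinParams,
    SpotParams,
    add_noise,
    apply_foundation,
    generate_scene,
    skin_spectrum,
    spot_spectrum,
    study_table,
)


class TestSkinSpectrum:
    def test_default_curve_rises_red_over_blue(self):
        s = skin_spectrum(SkinParams())
        assert s.values[-1] > s.values[0]  # 730 nm above 420 nm

    def test_no_dips_gives_strictly_monotone_curve(self):
        s = skin_spectrum(SkinParams(hb_dip_540=0.0, hb_dip_575=0.0))
        assert np.all(np.diff(s.values) > 0)

    def test_monotone_outside_dip_windows(self):
        s = skin_spectrum(SkinParams())
        wl = s.grid.wavelengths_nm
        outside = (wl < 500.0) | (wl > 620.0)
        diffs = np.diff(s.values)
        assert np.all(diffs[outside[:-1] & outside[1:]] > 0)

    def test_all_model_presets_rise_and_stay_in_unit_interval(self):
        assert len(MODEL_PRESETS) == 9
        for cfg in MODEL_PRESETS.values():
            s = skin_spectrum(cfg.skin)
            assert s.values[-1] > s.values[0]
            assert np.all((s.values > 0) & (s.values < 1))

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            skin_spectrum(SkinParams(r_min=0.9, r_max=1.4))


class TestSpotSpectrum:
    def test_zero_melanin_is_identity(self):
        base = skin_spectrum(SkinParams())
        np.testing.assert_array_equal(spot_spectrum(base, 0.0).values, base.values)

    def test_angle_to_base_increases_with_melanin(self):
        base = skin_spectrum(SkinParams())
        angles = [
            spectral_angle(base, spot_spectrum(base, m))
            for m in np.arange(0.1, 1.01, 0.1)
        ]
        assert np.all(np.diff(angles) > 0)

    def test_attenuation_stronger_at_blue_end(self):
        base = skin_spectrum(SkinParams())
        spot = spot_spectrum(base, 0.3)
        ratio = spot.values / base.values
        assert ratio[0] < ratio[-1]


class TestApplyFoundation:
    def test_zero_opacity_is_identity(self, grid, rng):
        cube = Datacube(rng.uniform(0.1, 0.9, (4, 4, 32)), grid)
        shade = skin_spectrum(SkinParams(), grid)
        np.testing.assert_array_equal(
            apply_foundation(cube, shade, 0.0).data, cube.data
        )

    def test_full_opacity_replaces_every_pixel_with_shade(self, grid, rng):
        cube = Datacube(rng.uniform(0.1, 0.9, (4, 4, 32)), grid)
        shade = skin_spectrum(SkinParams(), grid)
        out = apply_foundation(cube, shade, 1.0)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(shade.values, out.data.shape), atol=1e-15
        )

    def test_half_opacity_is_exact_midpoint(self, grid):
        u = np.full(32, 0.2)
        cube = Datacube(u[None, None, :], grid)
        shade = Spectrum(np.full(32, 0.6), grid)
        out = apply_foundation(cube, shade, 0.5)
        np.testing.assert_allclose(out.data[0, 0], 0.4, atol=1e-15)

    def test_invalid_opacity_rejected(self, grid):
        cube = Datacube(np.full((1, 1, 32), 0.5), grid)
        shade = Spectrum(np.full(32, 0.5), grid)
        with pytest.raises(ValueError):
            apply_foundation(cube, shade, 1.5)


class TestAddNoise:
    def test_same_seed_reproduces_exactly(self, grid, rng):
        cube = Datacube(rng.uniform(0.1, 0.9, (8, 8, 32)), grid)
        a = add_noise(cube, 47.0, seed=5)
        b = add_noise(cube, 47.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empirical_snr_matches_target(self, grid):
        cube = Datacube(np.full((100, 100, 1), 0.5), default_grid().__class__(np.array([550.0])))
        noisy = add_noise(cube, 47.0, seed=0)
        rel = noisy.data / 0.5 - 1.0
        snr_est = 1.0 / rel.std()
        assert snr_est == pytest.approx(47.0, rel=0.05)

    def test_huge_snr_is_noiseless_limit(self, grid, rng):
        cube = Datacube(rng.uniform(0.1, 0.9, (4, 4, 32)), grid)
        out = add_noise(cube, 1e12, seed=1)
        np.testing.assert_allclose(out.data, cube.data, atol=1e-9)

    def test_never_produces_negative_reflectance(self, grid):
        cube = Datacube(np.full((20, 20, 32), 0.01), grid)
        out = add_noise(cube, 1.0, seed=2)  # brutal noise to force clipping
        assert np.all(out.data >= 0.0)


class TestGenerateScene:
    def test_no_spots_no_mottle_no_noise_is_uniform(self, ref_roi, work_roi):
        cfg = SimConfig(
            seed=0,
            snr=None,
            skin=SkinParams(mottle_sd=0.0),
            spots=SpotParams(n_spots=0),
        )
        scene = generate_scene(cfg)
        from samcover.angles import angle_map, summarize

        amap = angle_map(
            scene.cube_T0, work_roi, mean_spectrum(scene.cube_T0, ref_roi)
        )
        assert summarize(amap).mu_theta_deg == pytest.approx(0.0, abs=1e-9)
        assert not scene.spot_mask.any()

    def test_spot_mask_matches_recorded_disks(self):
        scene = generate_scene(SimConfig(seed=3))
        h, w = scene.spot_mask.shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        rebuilt = np.zeros((h, w), dtype=bool)
        for spot in scene.truth["spots"]:
            rebuilt |= (rows - spot["row"]) ** 2 + (cols - spot["col"]) ** 2 <= spot[
                "radius_px"
            ] ** 2
        np.testing.assert_array_equal(scene.spot_mask, rebuilt)

    def test_scene_is_seed_reproducible(self):
        a = generate_scene(SimConfig(seed=9))
        b = generate_scene(SimConfig(seed=9))
        np.testing.assert_array_equal(a.cube_T0.data, b.cube_T0.data)
        np.testing.assert_array_equal(a.cube_Timm.data, b.cube_Timm.data)

    def test_spots_darken_the_scene_locally(self):
        scene = generate_scene(SimConfig(seed=4, snr=None))
        t0 = scene.cube_T0.data
        inside = t0[scene.spot_mask].mean()
        outside = t0[~scene.spot_mask].mean()
        assert inside < outside

    def test_oversized_spot_rejected(self):
        cfg = SimConfig(
            size_px=(24, 24), spots=SpotParams(n_spots=1, radius_mm=(4.0, 4.0))
        )
        with pytest.raises(ValueError, match="radius"):
            generate_scene(cfg)


class TestStudyTable:
    def test_full_study_is_consumable_by_stats_and_ranks_products(self):
        table, results = study_table(seed=1)
        frame = table.frame
        assert len(results) == 27  # 9 models x 3 products
        assert set(frame["product"]) == set(PRODUCT_PRESETS)
        means = (
            frame[frame["metric"] == "alpha_hf"].groupby("product")["value"].mean()
        )
        # mean homogeneity factor must order as the ground-truth opacities
        assert means["Low"] < means["Medium"] < means["High"]

    def test_larger_initial_contrast_gives_larger_alpha(self, ref_roi, work_roi):
        """Scenes with more initial inhomogeneity show a larger homogeneity
        change at fixed opacity (positive mu_theta(T0) - alpha relation)."""
        from samcover.coverage import evaluate_pair
        from samcover.stats import correlate

        mus, alphas = [], []
        for i, mel_hi in enumerate([0.05, 0.15, 0.25, 0.35, 0.45]):
            cfg = SimConfig(
                seed=100 + i,
                snr=None,
                spots=SpotParams(n_spots=14, melanin=(0.8 * mel_hi, mel_hi)),
                product=ProductParams(name="mid", opacity=0.5),
            )
            scene = generate_scene(cfg)
            res = evaluate_pair(scene.cube_T0, scene.cube_Timm, ref_roi, work_roi)
            mus.append(res.mu_roi_T0)
            alphas.append(res.alpha_hf)
        r, _ = correlate(mus, alphas)
        assert r > 0.0
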