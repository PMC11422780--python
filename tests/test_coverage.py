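"""Coverage statistics: worked-example arithmetic, analytic limits,
recovery on synthetic ground truth."""

import numpy as np
import pytest

from samcover.angles import Spectrum, mean_spectrum, spectral_angle, summarize, angle_map
from samcover.coverage import (
    contrast_reduction,
    delta_mu,
    evaluate_pair,
    homogeneity_factor,
    peak_positions,
    spectral_shift_factor,
)
from samcover.datacube import Datacube
from samcover.roi import ROI
from samcover.synth import ProductParams, SimConfig, generate_scene


class TestHomogeneityFactor:
    def test_no_change_is_zero(self):
        assert homogeneity_factor(2.5, 2.5) == 0.0

    def test_perfect_homogeneity_limit_is_100(self):
        assert homogeneity_factor(2.88, 0.0) == 100.0

    def test_printed_means_give_16_7_percent(self):
        # 100 * (1 - 2.40 / 2.88)
        assert homogeneity_factor(2.88, 2.40) == pytest.approx(16.667, abs=1e-3)

    def test_homogeneity_loss_is_negative(self):
        assert homogeneity_factor(2.0, 3.0) < 0.0

    def test_zero_t0_mean_raises(self):
        with pytest.raises(ValueError):
            homogeneity_factor(0.0, 1.0)


class TestSpectralShiftFactor:
    def test_equal_inputs_give_zero(self):
        assert spectral_shift_factor(2.3, 2.3) == 0.0

    def test_printed_shift(self):
        # mu@T0(Timm) = 5.52, mu@T0(T0) = 2.30 -> 3.22 degrees
        assert spectral_shift_factor(5.52, 2.30) == pytest.approx(3.22)

    def test_sign_not_clamped(self):
        assert spectral_shift_factor(1.0, 2.0) == -1.0


class TestDeltaMu:
    def test_printed_means_give_minus_048(self):
        assert delta_mu(2.40, 2.88) == pytest.approx(-0.48)

    def test_sign_convention(self):
        assert delta_mu(3.0, 2.5) == pytest.approx(0.5)
        assert delta_mu(2.5, 2.5) == 0.0


class TestContrastReduction:
    def test_printed_contrasts_give_about_66_percent(self):
        res = contrast_reduction(3.0, 1.0)
        assert res.reduction_percent == pytest.approx(66.667, abs=1e-2)

    def test_no_change_and_perfect_hiding(self):
        assert contrast_reduction(2.0, 2.0).reduction_percent == 0.0
        assert contrast_reduction(2.0, 0.0).reduction_percent == 100.0

    def test_zero_pre_contrast_raises(self):
        with pytest.raises(ValueError):
            contrast_reduction(0.0, 1.0)


class TestEvaluatePair:
    def test_identity_product_gives_exact_zeros(self, noisy_scene, ref_roi, work_roi):
        cube = noisy_scene.cube_T0
        res = evaluate_pair(cube, cube, ref_roi, work_roi)
        assert res.alpha_hf == 0.0
        assert res.beta_sf == 0.0
        assert res.delta_mu_theta == 0.0

    def test_global_scaling_invariance(self, noisy_scene, ref_roi, work_roi):
        t0, timm = noisy_scene.cube_T0, noisy_scene.cube_Timm
        res1 = evaluate_pair(t0, timm, ref_roi, work_roi)
        scale = 1.8
        res2 = evaluate_pair(
            Datacube(scale * t0.data, t0.grid, t0.pixel_pitch_um),
            Datacube(scale * timm.data, timm.grid, timm.pixel_pitch_um),
            ref_roi,
            work_roi,
        )
        assert res2.alpha_hf == pytest.approx(res1.alpha_hf, abs=1e-8)
        assert res2.beta_sf == pytest.approx(res1.beta_sf, abs=1e-10)

    def test_full_opacity_noiseless_reaches_alpha_100(
        self, noiseless_full_opacity_scene, ref_roi, work_roi
    ):
        scene = noiseless_full_opacity_scene
        res = evaluate_pair(scene.cube_T0, scene.cube_Timm, ref_roi, work_roi)
        assert res.alpha_hf == pytest.approx(100.0, abs=1e-6)

    def test_full_opacity_beta_matches_closed_form(
        self, noiseless_full_opacity_scene, ref_roi, work_roi
    ):
        # At opacity 1 every Timm spectrum equals the shade, so
        # mu@T0(Timm) is exactly angle(shade, reference at T0).
        scene = noiseless_full_opacity_scene
        res = evaluate_pair(scene.cube_T0, scene.cube_Timm, ref_roi, work_roi)
        shade = Spectrum(np.asarray(scene.truth["shade_values"]), scene.cube_T0.grid)
        ref_T0 = mean_spectrum(scene.cube_T0, ref_roi)
        expected = spectral_angle(ref_T0, shade) - res.mu_roiT0_T0
        assert res.beta_sf == pytest.approx(expected, abs=1e-9)

    def test_uniform_skin_closed_form_beta_is_skin_to_shade_angle(
        self, ref_roi, work_roi
    ):
        from samcover.synth import SkinParams, SpotParams

        cfg = SimConfig(
            seed=1,
            snr=None,
            skin=SkinParams(mottle_sd=0.0),
            spots=SpotParams(n_spots=0),
            product=ProductParams(name="full", opacity=1.0),
        )
        scene = generate_scene(cfg)
        res = evaluate_pair(scene.cube_T0, scene.cube_Timm, ref_roi, work_roi)
        shade = Spectrum(np.asarray(scene.truth["shade_values"]), scene.cube_T0.grid)
        skin = mean_spectrum(scene.cube_T0, ref_roi)
        assert res.beta_sf == pytest.approx(spectral_angle(skin, shade), abs=1e-6)
        # T0 is perfectly uniform: alpha is undefined, flagged not raised
        assert np.isnan(res.alpha_hf)
        assert "degenerate_t0_uniform_scene" in res.qc_flags

    def test_alpha_strictly_increases_with_opacity(self, ref_roi, work_roi):
        alphas = []
        for opacity in (0.2, 0.5, 0.8):
            scene = generate_scene(
                SimConfig(
                    seed=11,
                    snr=None,
                    product=ProductParams(name=f"o{opacity}", opacity=opacity),
                )
            )
            res = evaluate_pair(scene.cube_T0, scene.cube_Timm, ref_roi, work_roi)
            alphas.append(res.alpha_hf)
        assert alphas[0] < alphas[1] < alphas[2]

    def test_grid_mismatch_raises(self, noisy_scene, ref_roi, work_roi):
        from samcover.datacube import WavelengthGrid

        t0 = noisy_scene.cube_T0
        other = Datacube(
            t0.data,
            WavelengthGrid(t0.grid.wavelengths_nm + 1.0),
            t0.pixel_pitch_um,
        )
        with pytest.raises(ValueError, match="grid"):
            evaluate_pair(t0, other, ref_roi, work_roi)


class TestPeakPositions:
    @staticmethod
    def _summary_from_angles(values, bin_width=0.1):
        from samcover.angles import AngleMap

        n = values.size
        side = int(np.ceil(np.sqrt(n)))
        padded = np.full(side * side, values.mean())
        padded[:n] = values
        theta = padded.reshape(side, side)
        from samcover.datacube import default_grid

        ref = Spectrum(np.full(32, 0.5), default_grid())
        amap = AngleMap(theta_deg=theta, roi=ROI("r", 0, 0, side, side), reference=ref)
        return summarize(amap, bin_width_deg=bin_width)

    def test_unimodal_histogram_gives_one_peak_at_mode(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(2.0, 0.3, 4096))
        peaks = peak_positions(self._summary_from_angles(values))
        assert len(peaks) >= 1
        # dominant peak near the mode, carrying most of the mass
        pos, frac = max(peaks, key=lambda p: p[1])
        assert pos == pytest.approx(2.0, abs=0.3)
        assert frac > 0.5

    def test_two_separated_gaussians_recovered(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.normal(1.0, 0.15, 3000), rng.normal(5.0, 0.15, 1000)]
        )
        values = np.abs(values)
        peaks = peak_positions(
            self._summary_from_angles(values), min_separation_deg=1.0
        )
        big = sorted(peaks, key=lambda p: -p[1])[:2]
        positions = sorted(p for p, _ in big)
        assert positions[0] == pytest.approx(1.0, abs=0.2)
        assert positions[1] == pytest.approx(5.0, abs=0.2)
        # first peak (base skin) carries ~3/4 of the mass
        fracs = {round(p): f for p, f in big}
        assert fracs[1] > fracs[5]

    def test_close_gaussians_merge_into_one_peak(self):
        rng = np.random.default_rng(7)
        values = np.abs(
            np.concatenate([rng.normal(2.0, 0.2, 2000), rng.normal(2.5, 0.2, 2000)])
        )
        peaks = peak_positions(
            self._summary_from_angles(values), min_separation_deg=1.0
        )
        assert len(peaks) == 1
        assert peaks[0][1] == pytest.approx(1.0)
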