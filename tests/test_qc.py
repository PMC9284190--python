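"""Acquisition QC: SNR, CV, focus scoring, bead calibration."""

import math

import numpy as np
import pytest

import pentaplex as px


class TestSNR:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.img = rng.normal(10.0, 1.0, (100, 100))
        self.fg = np.zeros((100, 100), bool); self.fg[:20] = True
        self.bg = np.zeros((100, 100), bool); self.bg[50:] = True

    def test_equal_levels_give_zero(self):
        assert abs(px.snr(self.img, self.fg, self.bg)) < 0.1

    def test_k_sigma_offset_gives_k(self):
        img = self.img.copy()
        bg_sd = img[self.bg].std(ddof=1)
        img[self.fg] += 5 * bg_sd
        assert px.snr(img, self.fg, self.bg) == pytest.approx(5.0, abs=0.15)

    def test_constant_offset_invariance(self):
        a = px.snr(self.img, self.fg, self.bg)
        b = px.snr(self.img + 123.4, self.fg, self.bg)
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_background_spread_flagged_infinite(self):
        img = np.zeros((10, 10)); img[:5] = 7.0
        fg = np.zeros((10, 10), bool); fg[:5] = True
        assert math.isinf(px.snr(img, fg, ~fg))

    def test_overlapping_or_empty_masks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            px.snr(self.img, self.fg, self.fg)
        with pytest.raises(ValueError, match="non-empty"):
            px.snr(self.img, np.zeros((100, 100), bool), self.bg)

    def test_bead_snr_matches_noise_model_prediction(self, A):
        """Rendered bead SNR agrees with the closed-form prediction
        from the camera noise model within 10%."""
        read_sd = 3.0
        noise = px.NoiseModel(read_noise_sd=read_sd, dark_offset=100.0,
                              shot_noise=True, seed=12)
        level = 400.0
        stack, truth = px.generate_bead_slide(
            60, {"DAPI": level}, A, noise, seed=12
        )
        planes = np.clip(stack.stained - stack.dark_planes(), 0, None)
        i = list(stack.led_names).index("L385")
        plane = planes[3 * i + 2]  # L385:B is DAPI's unit entry
        fg = np.zeros(plane.shape, bool)
        rr, cc = np.mgrid[: plane.shape[0], : plane.shape[1]]
        for _, b in truth.iterrows():
            fg |= (rr - b.row) ** 2 + (cc - b.col) ** 2 <= 2.0**2  # bead cores
        bg = ~(
            (rr[:, :, None] - truth.row.values) ** 2
            + (cc[:, :, None] - truth.col.values) ** 2
            <= 8.0**2
        ).any(axis=2)
        measured = px.snr(plane, fg, bg)
        # background: clipped read noise; signal: level (unit fingerprint entry)
        # dark-subtracted bg pixels are max(N(0, read_sd), 0): sd of the
        # clipped half-normal is read_sd * sqrt((pi-1)/pi) about its mean
        clipped_sd = read_sd * math.sqrt((math.pi - 1) / math.pi)
        predicted = (level - read_sd / math.sqrt(2 * math.pi)) / clipped_sd
        assert measured == pytest.approx(predicted, rel=0.10)


class TestCV:
    def test_constant_values_zero(self):
        assert px.cv(np.full(10, 3.3)) == 0.0

    def test_two_point_sample_sd_convention(self):
        # {9, 11}: mean 10, sample sd sqrt(2) -> 14.1%
        assert px.cv(np.array([9.0, 11.0])) == pytest.approx(14.142, abs=0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0, 0.1, 200)
        assert px.cv(vals) == pytest.approx(px.cv(vals * 55.0), rel=1e-12)

    def test_lognormal_cells_have_expected_cv(self):
        """Per-cell intensities with 4% log-sd give CV near 4%."""
        rng = np.random.default_rng(7)
        vals = rng.lognormal(mean=np.log(100), sigma=0.04, size=5000)
        assert px.cv(vals) == pytest.approx(4.0, abs=0.4)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            px.cv(np.array([1.0]))
        with pytest.raises(ValueError, match="zero mean"):
            px.cv(np.array([-1.0, 1.0]))


class TestFocus:
    def test_constant_image_scores_zero(self):
        assert px.focus_score(np.full((32, 32), 5.0)) == 0.0

    def test_blur_strictly_reduces_score(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (128, 128))
        s0 = px.focus_score(img)
        s2 = px.focus_score(gaussian_filter(img, 2.0))
        s4 = px.focus_score(gaussian_filter(img, 4.0))
        assert s0 > s2 > s4

    def test_ranking_invariant_under_linear_rescale(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(1)
        planes = [gaussian_filter(rng.uniform(0, 1, (64, 64)), s) for s in (0, 1, 2, 3)]
        order1 = np.argsort([px.focus_score(p) for p in planes])
        order2 = np.argsort([px.focus_score(3.7 * p + 11) for p in planes])
        np.testing.assert_array_equal(order1, order2)

    def test_select_focus_plane_with_ties(self):
        img = np.random.default_rng(2).uniform(0, 1, (32, 32))
        stack = px.FocusStack(planes=(img, img.copy()))
        idx, scores = px.select_focus_plane(stack)
        assert idx == 0  # tie -> lower index
        const = np.zeros((32, 32))
        idx, _ = px.select_focus_plane(px.FocusStack(planes=(const, const + 1.0)))
        assert idx == 0  # both score 0

    def test_seven_plane_sweep_finds_focus(self, small_scene, panel, A):
        stack = px.render_acquisition(small_scene, panel, 1, A, px.NoiseModel(seed=6))
        dapi = stack.dapi_window_image()
        planes = px.defocus_stack(dapi, n_planes=7, focus_index=3, noise_sd=0.5, seed=6)
        idx, scores = px.select_focus_plane(px.FocusStack(planes=tuple(planes)))
        assert idx == 3
        assert scores[0] < scores[1] < scores[2] < scores[3]
        assert scores[3] > scores[4] > scores[5] > scores[6]

    def test_stack_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            px.FocusStack(planes=(np.zeros((4, 4)),))


class TestCalibration:
    def test_bright_beads_pass(self, A):
        stack, _ = px.generate_bead_slide(
            40, {f: 300.0 for f in A.col_labels}, A, px.NoiseModel(seed=9), seed=9
        )
        report = px.calibration_check(stack, {led: (10.0, 30.0) for led in A.led_names})
        assert report.passed, report.reasons

    def test_noise_only_slide_fails_no_beads(self, A):
        stack, _ = px.generate_bead_slide(
            1, {"DAPI": 0.0}, A, px.NoiseModel(seed=9), seed=9, shape=(128, 128)
        )
        report = px.calibration_check(stack, {led: (5.0, 50.0) for led in A.led_names})
        assert not report.passed
        assert any("no beads" in r for r in report.reasons)

    def test_dim_channel_fails_only_that_channel(self, A):
        """Dropping one LED's effective output (dim AF488 beads against
        unchanged camera noise) trips only that LED's SNR bound."""
        intensities = {f: 300.0 for f in A.col_labels}
        intensities["AF488"] = 8.0  # AF488 signal lives in the L470 rows
        stack, _ = px.generate_bead_slide(
            40, intensities, A, px.NoiseModel(seed=9), seed=9
        )
        thresholds = {led: (20.0, 30.0) for led in stack.led_names}
        report = px.calibration_check(stack, thresholds)
        assert not report.channels["L470"]["pass"]
        assert not report.passed
        for led in stack.led_names:
            if led != "L470":
                assert report.channels[led]["pass"], (led, report.channels[led])
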