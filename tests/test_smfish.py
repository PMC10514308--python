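"""Tests of smFISH preprocessing, spot fitting, calibration and gating."""

import numpy as np
import pandas as pd
import pytest

from burstfish import (
    CalibrationResult,
    PreprocessSettings,
    SpotFit,
    calibrate_single_transcript,
    fit_gaussian_2d,
    gate_crystal_cells,
    nascent_rna_count,
    nascent_tally,
    preprocess_stack,
    transcripts_per_cell,
)
from burstfish.exceptions import ArgumentError, CalibrationError, GatingError
from burstfish.smfish import detect_and_fit_spots, integrate_cell_intensities
from burstfish.synthetic import place_nonoverlapping_spots, render_spot_image

FAST = PreprocessSettings(blur_radius=1.0, ball_radius=15.0, z_bin=1)


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        out = preprocess_stack(np.full((64, 64), 37.0), FAST)
        assert np.allclose(out, 0.0)

    def test_z_binning_by_seven_reduces_21_planes_to_3(self):
        stack = np.random.default_rng(0).random((21, 32, 32))
        out = preprocess_stack(
            stack, PreprocessSettings(blur_radius=1.0, ball_radius=5.0, z_bin=7)
        )
        assert out.shape == (3, 32, 32)
        assert (out >= 0).all()

    def test_bin_factor_beyond_depth_is_rejected(self):
        with pytest.raises(ArgumentError):
            preprocess_stack(np.zeros((3, 16, 16)), PreprocessSettings(z_bin=7))

    def test_spot_intensities_survive_gradient_background(self):
        shape = (192, 192)
        centers = place_nonoverlapping_spots(30, shape, margin=12, min_dist=14, seed=2)
        rr, cc = np.indices(shape)
        gradient = 20.0 + 0.15 * rr + 0.1 * cc
        img, truth = render_spot_image(
            [(r, c, 100.0, 1.5, 1.5) for r, c in centers], shape, background=gradient
        )
        proc = preprocess_stack(img, FAST)
        for (r, c), expected in zip(centers, truth.integrated_intensity):
            r, c = int(round(r)), int(round(c))
            window = proc[r - 6 : r + 7, c - 6 : c + 7].sum()
            assert abs(window - expected) / expected < 0.10


class TestStackIO:
    def test_tiff_roundtrip_preserves_stack(self, tmp_path, rng):
        from burstfish.smfish import read_stack, write_stack

        stack = rng.random((4, 16, 16)).astype(np.float32)
        path = tmp_path / "stack.tif"
        write_stack(path, stack)
        back = read_stack(path)
        assert back.shape == stack.shape
        assert np.allclose(back, stack)


class TestGaussianFit:
    def test_noiseless_spot_recovered_exactly(self):
        img, truth = render_spot_image([(20, 25, 100, 1.5, 1.5)], (48, 48),
                                       background=10.0)
        fit = fit_gaussian_2d(img)
        assert fit.ok
        assert fit.center[0] == pytest.approx(20.0, abs=1e-6)
        assert fit.center[1] == pytest.approx(25.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.background == pytest.approx(10.0, rel=1e-6)
        assert fit.integrated_intensity == pytest.approx(
            truth.integrated_intensity[0], rel=1e-6
        )

    def test_poisson_noise_keeps_intensity_within_ten_percent(self):
        ok = 0
        for seed in range(60):
            img, truth = render_spot_image(
                [(20, 25, 100, 1.5, 1.5)], (48, 48), background=10.0,
                noise="poisson", seed=seed,
            )
            fit = fit_gaussian_2d(img)
            if fit.ok and abs(
                fit.integrated_intensity - truth.integrated_intensity[0]
            ) / truth.integrated_intensity[0] < 0.10:
                ok += 1
        assert ok >= 57  # 95% of seeds

    def test_flat_patch_flags_failure(self):
        fit = fit_gaussian_2d(np.full((9, 9), 5.0))
        assert not fit.ok
        assert fit.reason

    def test_undersized_patch_rejected(self):
        with pytest.raises(ArgumentError):
            fit_gaussian_2d(np.zeros((5, 5)))


class TestCalibration:
    def _spot(self, intensity, ok=True):
        # sigma_x = sigma_y = 1: integrated = 2*pi*A
        return SpotFit((0, 0), (1.0, 1.0), intensity / (2 * np.pi), 0.0, 0.0, ok)

    def test_identical_spots_give_zero_cv(self):
        cal = calibrate_single_transcript([self._spot(10.0)] * 100)
        assert cal.mean_intensity == pytest.approx(10.0)
        assert cal.cv == 0.0
        assert cal.n_spots == 100

    def test_lognormal_spread_mean_within_three_se(self, rng):
        vals = rng.lognormal(np.log(500.0), 0.3, 400)
        cal = calibrate_single_transcript([self._spot(v) for v in vals])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(cal.mean_intensity - vals.mean()) < 3 * se

    def test_failed_fits_are_excluded_and_all_failed_errors(self):
        spots = [self._spot(10.0), self._spot(999.0, ok=False)]
        assert calibrate_single_transcript(spots).mean_intensity == pytest.approx(10.0)
        with pytest.raises(CalibrationError):
            calibrate_single_transcript([self._spot(10.0, ok=False)])

    def test_transcripts_per_cell_is_the_intensity_quotient(self):
        cal = CalibrationResult(10.0, 0.1, 50)
        assert transcripts_per_cell(7200.0, cal) == pytest.approx(720.0)
        assert transcripts_per_cell(0.0, cal) == 0.0
        assert transcripts_per_cell(7204.0, cal, rounding="nearest") == 720.0
        with pytest.raises(ArgumentError):
            transcripts_per_cell(-1.0, cal)

    def test_nascent_rna_count_ratio_and_skip(self):
        cal = CalibrationResult(10.0, 0.1, 50)
        assert nascent_rna_count(self._spot(120.0), cal) == pytest.approx(12.0)
        assert nascent_rna_count(self._spot(120.0, ok=False), cal) is None


class TestGating:
    def _records(self, marker):
        return pd.DataFrame(
            {"marker_intensity": marker, "nascent_intensity": 0.0}
        )

    def test_bimodal_marker_recovers_planted_labels(self, rng):
        low = rng.lognormal(np.log(1.0), 0.3, 200)
        high = rng.lognormal(np.log(100.0), 0.3, 150)
        rec = self._records(np.concatenate([low, high]))
        gated = gate_crystal_cells(rec)
        labels = gated["gate_label"].to_numpy()
        assert (labels[:200] == "other").all()
        assert (labels[200:] == "crystal").all()

    def test_manual_threshold_matches_otsu_on_separable_mixture(self, rng):
        low = rng.lognormal(np.log(1.0), 0.3, 200)
        high = rng.lognormal(np.log(100.0), 0.3, 150)
        rec = self._records(np.concatenate([low, high]))
        otsu = gate_crystal_cells(rec)
        manual = gate_crystal_cells(rec, policy="manual", manual_threshold=10.0)
        assert (otsu["gate_label"] == manual["gate_label"]).all()

    def test_labels_invariant_to_intensity_rescaling(self, rng):
        low = rng.lognormal(np.log(1.0), 0.3, 200)
        high = rng.lognormal(np.log(100.0), 0.3, 150)
        marker = np.concatenate([low, high])
        a = gate_crystal_cells(self._records(marker))
        b = gate_crystal_cells(self._records(marker * 37.5))
        assert (a["gate_label"] == b["gate_label"]).all()

    def test_degenerate_marker_warns_and_labels_other(self):
        with pytest.warns(UserWarning, match="degenerate"):
            gated = gate_crystal_cells(self._records(np.full(50, 3.0)))
        assert (gated["gate_label"] == "other").all()

    def test_tally_counts_nascent_crystal_cells(self, rng):
        rec = pd.DataFrame(
            {
                "gate_label": ["crystal"] * 184 + ["other"] * 50,
                "nascent_intensity": np.concatenate(
                    [np.full(75, 100.0), np.zeros(109), np.full(50, 100.0)]
                ),
            }
        )
        tally = nascent_tally(rec, detection_threshold=30.0)
        assert (tally.n_nascent, tally.n_empty) == (75, 109)

    def test_tally_without_crystal_cells_errors(self):
        rec = pd.DataFrame({"gate_label": ["other"] * 5, "nascent_intensity": 0.0})
        with pytest.raises(GatingError):
            nascent_tally(rec, detection_threshold=1.0)


class TestEndToEndCounting:
    def _calibration(self):
        centers = place_nonoverlapping_spots(
            20, (192, 192), margin=12, min_dist=16.0, seed=9
        )
        img, _ = render_spot_image(
            [(r, c, 50.0, 1.4, 1.4) for r, c in centers], (192, 192),
            background=10.0, noise="gaussian", noise_sigma=1.0, seed=10,
        )
        proc = preprocess_stack(img, FAST)
        return calibrate_single_transcript(
            detect_and_fit_spots(proc, patch_radius=6, min_distance=8)
        )

    @pytest.mark.parametrize(
        "n_true,shape", [(10, (96, 96)), (50, (192, 192)), (720, (256, 256))]
    )
    def test_known_transcript_numbers_recovered_within_five_percent(
        self, n_true, shape
    ):
        calib = self._calibration()
        centers = place_nonoverlapping_spots(n_true, shape, margin=10,
                                             min_dist=7.0, seed=4)
        img, _ = render_spot_image(
            [(r, c, 50.0, 1.4, 1.4) for r, c in centers], shape,
            background=10.0, noise="gaussian", noise_sigma=1.0, seed=5,
        )
        proc = preprocess_stack(img, FAST)
        total = integrate_cell_intensities(
            proc, np.ones(shape, dtype=int), threshold=1.0
        ).total_intensity[0]
        est = transcripts_per_cell(total, calib)
        assert abs(est - n_true) / n_true < 0.05

    def test_counts_invariant_under_global_intensity_doubling(self):
        """The estimate is a ratio, so scaling the illumination cancels."""
        shape = (192, 192)
        centers = place_nonoverlapping_spots(50, shape, margin=10, min_dist=7.0,
                                             seed=4)
        cal_centers = place_nonoverlapping_spots(20, shape, margin=12,
                                                 min_dist=16.0, seed=9)
        estimates = []
        for scale in (1.0, 2.0):
            cal_img, _ = render_spot_image(
                [(r, c, 50.0 * scale, 1.4, 1.4) for r, c in cal_centers], shape,
                background=10.0 * scale,
            )
            calib = calibrate_single_transcript(
                detect_and_fit_spots(preprocess_stack(cal_img, FAST),
                                     patch_radius=6, min_distance=8)
            )
            img, _ = render_spot_image(
                [(r, c, 50.0 * scale, 1.4, 1.4) for r, c in centers], shape,
                background=10.0 * scale,
            )
            total = integrate_cell_intensities(
                preprocess_stack(img, FAST), np.ones(shape, dtype=int),
                threshold=0.5 * scale,
            ).total_intensity[0]
            estimates.append(transcripts_per_cell(total, calib))
        # the rolling ball's intensity semi-axis is not scale-equivariant,
        # but the calibration ratio cancels it to sub-percent level
        assert estimates[0] == pytest.approx(estimates[1], rel=0.01)

    def test_overlapping_nascent_blob_counts_its_transcripts(self):
        """A nascent site rendered as k overlapping unit spots reads out
        approximately k RNAs."""
        k = 8
        rng = np.random.default_rng(6)
        jitter = rng.uniform(-0.6, 0.6, size=(k, 2))
        spots = [(24 + dr, 24 + dc, 50.0, 1.4, 1.4) for dr, dc in jitter]
        img, _ = render_spot_image(spots, (48, 48), background=10.0)
        fit = fit_gaussian_2d(img)
        cal = CalibrationResult(2 * np.pi * 50.0 * 1.4 * 1.4, 0.0, 10)
        est = nascent_rna_count(fit, cal)
        assert est == pytest.approx(k, rel=0.15)
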