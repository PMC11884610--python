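import math

import numpy as np
import pytest

from deepsm.analysis import (
    DETECTION_LIMIT_DB,
    calibration_curve,
    compute_snr_db,
    detect_particles,
    fit_snr_distribution,
    frame_average,
    snr_db_from_stats,
    subtract_background,
)
from deepsm.optics import ParticleState, calibrate_amplitude_coeff
from deepsm.simulate import (
    EventSchedule,
    ImageSequence,
    NoiseModel,
    ParticleScene,
    simulate_sequence,
)


class TestSubtractBackground:
    def test_identical_gives_zero(self, rng):
        bg = rng.uniform(50, 150, size=(16, 16))
        seq = ImageSequence(np.stack([bg, bg]))
        np.testing.assert_allclose(subtract_background(seq, bg), 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((2, 8, 8)), np.ones((9, 9)))

    def test_static_noise_scene_mean_zero(self, optical):
        noisy, _ = simulate_sequence(ParticleScene(), optical, NoiseModel(),
                                     64, (32, 32), seed=1)
        bg = np.full((32, 32), optical.background_level)
        diff = subtract_background(noisy, bg)
        per_pixel_mean = diff.mean(axis=0)
        se = math.sqrt(optical.background_level / 64)
        assert np.abs(per_pixel_mean).max() < 5 * se

    def test_linearity_with_averaging(self, rng):
        frames = rng.uniform(10, 20, size=(8, 8, 8))
        bg = rng.uniform(0, 5, size=(8, 8))
        a = frame_average(subtract_background(frames, bg), 4)
        b = subtract_background(frame_average(frames, 4), bg)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestFrameAverage:
    def test_identity_at_one(self, rng):
        frames = rng.normal(size=(5, 4, 4))
        np.testing.assert_array_equal(frame_average(frames, 1), frames)

    def test_constant_frames_unchanged(self):
        frames = np.full((8, 4, 4), 3.3)
        np.testing.assert_allclose(frame_average(frames, 4), 3.3)

    def test_block_count(self, rng):
        frames = rng.normal(size=(10, 4, 4))
        assert frame_average(frames, 4).shape == (2, 4, 4)

    def test_n_larger_than_t_rejected(self, rng):
        with pytest.raises(ValueError):
            frame_average(rng.normal(size=(3, 4, 4)), 4)

    def test_rolling_mode_length(self, rng):
        frames = rng.normal(size=(10, 4, 4))
        assert frame_average(frames, 4, rolling=True).shape[0] == 7

    def test_noise_shrinks_by_sqrt_n(self, rng):
        frames = rng.poisson(1000, size=(256, 32, 32)).astype(float) - 1000
        fa = frame_average(frames, 16)
        ratio = frames.std() / fa.std()
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestSnrDb:
    def test_three_sigma_is_detection_limit(self):
        assert snr_db_from_stats(3.0, 1.0) == pytest.approx(DETECTION_LIMIT_DB)
        assert DETECTION_LIMIT_DB == pytest.approx(20.0 * math.log10(3.0))

    def test_one_sigma_is_zero_db(self):
        assert snr_db_from_stats(1.0, 1.0) == pytest.approx(0.0)

    def test_ten_sigma_is_twenty_db(self):
        assert snr_db_from_stats(10.0, 1.0) == pytest.approx(20.0)

    def test_six_db_is_doubling(self):
        assert snr_db_from_stats(2.0, 1.0) == pytest.approx(6.0206, abs=1e-3)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            snr_db_from_stats(1.0, 0.0)

    def _image_with_peak(self, rng, peak_sigma):
        img = rng.normal(0.0, 1.0, size=(64, 64))
        img[32, 40] += peak_sigma
        return img

    def test_measured_three_sigma_close_to_limit(self, rng):
        img = self._image_with_peak(rng, 3.0 * 15)  # 15-row average dilutes
        rec = compute_snr_db(img, (40, 32), profile_height=15)
        assert rec.snr_db == pytest.approx(DETECTION_LIMIT_DB, abs=2.0)

    def test_affine_invariance(self, rng):
        img = self._image_with_peak(rng, 80.0)
        r1 = compute_snr_db(img, (40, 32))
        r2 = compute_snr_db(7.0 * img + 100.0, (40, 32))
        assert r2.snr_db == pytest.approx(r1.snr_db, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="SD is zero"):
            compute_snr_db(np.zeros((32, 32)), (16, 16))

    def test_explicit_background_region(self, rng):
        img = self._image_with_peak(rng, 60.0)
        mask = np.zeros((64, 64), bool)
        mask[:, :16] = True
        rec = compute_snr_db(img, (40, 32), bg_region=mask)
        assert rec.detected


class TestDetectParticles:
    def _noise_frame(self, optical, seed):
        rng = np.random.default_rng(seed)
        return rng.poisson(optical.background_level, size=(64, 64)).astype(
            float
        ) - optical.background_level

    def test_false_positive_rate_calibrated(self, optical):
        hits = sum(
            bool(detect_particles(self._noise_frame(optical, s), optical))
            for s in range(100)
        )
        assert hits / 100 < 0.05

    def test_injected_particle_detected(self, optical):
        coeff = calibrate_amplitude_coeff(15.0, 20.0, optical)
        p = ParticleState(x=40, y=32, amplitude=coeff * 8000, phase=0.0)
        found = 0
        scene = ParticleScene([(p, EventSchedule())])
        noisy, _ = simulate_sequence(scene, optical, NoiseModel(), 100,
                                     (64, 64), seed=21)
        for frame in noisy.frames:
            dets = detect_particles(frame - optical.background_level, optical)
            if any(np.hypot(x - 40, y - 32) < 5 for x, y in dets):
                found += 1
        assert found >= 95

    def test_two_separated_particles_both_found(self, optical):
        coeff = calibrate_amplitude_coeff(20.0, 20.0, optical)
        scene = ParticleScene()
        scene.add(ParticleState(x=24, y=20, amplitude=coeff * 8000, phase=0.0))
        scene.add(ParticleState(x=70, y=76, amplitude=coeff * 8000,
                                phase=0.58 * math.pi))
        noisy, _ = simulate_sequence(scene, optical, NoiseModel(), 4, (96, 96),
                                     seed=22)
        dets = detect_particles(noisy.frames[0] - optical.background_level,
                                optical)
        assert any(np.hypot(x - 24, y - 20) < 5 for x, y in dets)
        assert any(np.hypot(x - 70, y - 76) < 5 for x, y in dets)


class TestFitSnrDistribution:
    def test_recovers_gaussian_parameters(self, rng):
        mu_true, sd_true = 14.53, 1.09
        sample = rng.normal(mu_true, sd_true, size=1000)
        mu, sigma = fit_snr_distribution(sample)
        assert mu == pytest.approx(mu_true, abs=3 * sd_true / math.sqrt(1000))
        assert sigma == pytest.approx(sd_true, rel=0.15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_snr_distribution(np.full(20, 5.0))

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_snr_distribution(rng.normal(size=5))

    def test_two_point_symmetric_mean(self):
        a = 12.0
        sample = np.array([a - 1, a + 1] * 10)
        mu, _ = fit_snr_distribution(sample)
        assert mu == pytest.approx(a)

    def test_plot_export(self, rng, tmp_path):
        path = tmp_path / "hist.png"
        fit_snr_distribution(rng.normal(10, 2, size=100), plot_path=path)
        assert path.exists() and path.stat().st_size > 0


class TestCalibrationCurve:
    def test_strictly_increasing_means_end_to_end(self, optical):
        # cubic amplitude law spans 60 dB over 5-50 nm, so use a large frame
        # and a far background region to keep the top sizes unsaturated
        coeff = calibrate_amplitude_coeff(-4.0, 5.0, optical)
        yy, xx = np.mgrid[0:128, 0:128]
        dxg, dyg = xx - 80.0, yy - 64.0
        far_cone = (dxg <= -40) & (np.abs(dyg) <= 0.36 * np.abs(dxg))
        groups = {}
        for d in (5.0, 10.0, 20.0, 40.0, 50.0):
            p = ParticleState(x=80, y=64, amplitude=coeff * d**3, phase=0.0)
            scene = ParticleScene([(p, EventSchedule())])
            noisy, _ = simulate_sequence(scene, optical, NoiseModel(), 8,
                                         (128, 128), seed=int(d))
            groups[d] = [
                compute_snr_db(f - optical.background_level, (80, 64),
                               bg_region=far_cone).snr_db
                for f in noisy.frames
            ]
        curve = calibration_curve(groups)
        assert np.all(np.diff(curve.snr_mean_db) > 0)
        assert curve.slope > 0

    def test_flat_snrs_give_zero_slope(self):
        groups = {5.0: [10.0] * 5, 10.0: [10.0] * 5, 20.0: [10.0] * 5}
        curve = calibration_curve(groups)
        assert curve.slope == 0.0

    def test_order_invariance(self, rng):
        groups = {d: rng.normal(10 + d, 1, size=20) for d in (5.0, 10.0, 20.0)}
        c1 = calibration_curve(groups)
        c2 = calibration_curve(dict(reversed(list(groups.items()))))
        assert c1.slope == pytest.approx(c2.slope)
        np.testing.assert_allclose(c1.snr_mean_db, c2.snr_mean_db)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve({5.0: [1, 2], 10.0: [3, 4]})
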