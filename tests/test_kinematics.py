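"""Track reconstruction, smoothing, and the per-flight kinematic summaries."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import savgol_filter

import escapeflight as ef
from escapeflight.kinematics import (Track3D, TrackError, kalman_smooth,
                                     max_wingspan, reconstruct_track,
                                     trajectory_average_speed,
                                     wingbeat_frequency)

from escapeflight.synthgen import generate_cohort, synthesize_trajectory
from conftest import truth_by_trial


def linear_track(n=60, fps=400.0, velocity=(0.0, 0.0, 3.0), start=(0, 0, 0.3)):
    t = np.arange(n) / fps
    pos = np.asarray(start) + np.outer(t, velocity)
    return Track3D(times=t, positions=pos, residuals=np.zeros(n), fps=fps)


def make_recording(params, rig, speed=3.0, freq=23.0, seed=0):
    cohort = generate_cohort(params)
    bird = cohort[0]
    trial = ef.TrialPlan(trial_id="t", bird_id=bird.bird_id, test_day=1,
                         flight_index=1, body_mass_on_day_g=bird.body_mass_day1_g,
                         loading_real=18.0, true_speed=speed, true_freq=freq)
    return synthesize_trajectory(trial, rig, bird, params,
                                 rng=np.random.default_rng(seed))


class TestReconstruct:
    def test_noiseless_chain_is_exact(self, noisefree_params, rig, dlts):
        rec = make_recording(noisefree_params, rig)
        track = reconstruct_track(rec.pixel_tracks["beak"], dlts, rig.fps)
        np.testing.assert_allclose(track.positions,
                                   rec.truth_positions["beak"], atol=1e-6)

    def test_survives_losing_one_camera(self, noisefree_params, rig, dlts):
        rec = make_recording(noisefree_params, rig)
        tracks = rec.pixel_tracks["beak"].copy()
        tracks[0] = np.nan
        track = reconstruct_track(tracks, dlts, rig.fps)
        np.testing.assert_allclose(track.positions,
                                   rec.truth_positions["beak"], atol=1e-6)

    def test_default_noise_position_error(self, params, rig, dlts):
        errs = []
        for seed in range(10):
            rec = make_recording(params, rig, seed=seed)
            track = reconstruct_track(rec.pixel_tracks["beak"], dlts, rig.fps)
            errs.append(np.linalg.norm(
                track.positions - rec.truth_positions["beak"], axis=1))
        assert np.sqrt(np.mean(np.concatenate(errs) ** 2)) < 2e-3

    def test_short_gap_interpolated(self, noisefree_params, rig, dlts):
        rec = make_recording(noisefree_params, rig)
        tracks = rec.pixel_tracks["beak"].copy()
        tracks[:, 20:22, :] = np.nan  # 2-frame full dropout
        track = reconstruct_track(tracks, dlts, rig.fps)
        assert len(track.positions) == tracks.shape[1]
        np.testing.assert_allclose(track.positions,
                                   rec.truth_positions["beak"], atol=1e-4)

    def test_long_gap_splits_track(self, noisefree_params, rig, dlts):
        rec = make_recording(noisefree_params, rig)
        tracks = rec.pixel_tracks["beak"].copy()
        n = tracks.shape[1]
        tracks[:, 15:25, :] = np.nan  # 10-frame dropout splits the track
        track = reconstruct_track(tracks, dlts, rig.fps)
        assert "split" in track.qc_flags
        assert len(track.positions) == n - 25

    def test_too_short_segment_rejected(self, noisefree_params, rig, dlts):
        rec = make_recording(noisefree_params, rig)
        tracks = rec.pixel_tracks["beak"][:, :8, :]
        with pytest.raises(TrackError, match="frames"):
            reconstruct_track(tracks, dlts, rig.fps)


class TestKalmanSmooth:
    def test_exact_on_linear_motion(self):
        track = linear_track(velocity=(0.0, 0.0, 3.0))
        sm = kalman_smooth(track, process_noise=1.0, measurement_noise=1e-3)
        np.testing.assert_allclose(sm.velocities[:, 2], 3.0, atol=1e-6)
        np.testing.assert_allclose(sm.positions, track.positions, atol=1e-9)

    def test_unbiased_on_noisy_linear_motion(self, rng):
        """Mean velocity error over noisy replicates is below 1% of speed."""
        errors = []
        for _ in range(100):
            track = linear_track(n=80)
            noisy = replace(track, positions=track.positions
                            + rng.normal(0, 5e-4, track.positions.shape))
            sm = kalman_smooth(noisy, process_noise=1.0, measurement_noise=5e-4)
            errors.append(np.mean(sm.velocities[:, 2]) - 3.0)
        assert abs(np.mean(errors)) < 0.03

    def test_small_r_limit_returns_measurements(self, rng):
        track = linear_track(n=40)
        noisy = replace(track, positions=track.positions
                        + rng.normal(0, 1e-3, track.positions.shape))
        sm = kalman_smooth(noisy, process_noise=1.0, measurement_noise=1e-9)
        np.testing.assert_allclose(sm.positions, noisy.positions, atol=1e-6)

    def test_invalid_noise_rejected(self):
        track = linear_track()
        with pytest.raises(TrackError):
            kalman_smooth(track, process_noise=0.0)
        with pytest.raises(TrackError):
            kalman_smooth(track, measurement_noise=-1.0)

    def test_agrees_with_savgol_oracle_on_noisy_sinusoid(self):
        """Velocity from the smoother matches local-quadratic (Savitzky-Golay)
        differentiation to < 5% RMS on a noisy sinusoidal track.

        The smoother bandwidth is set from the signal itself: process noise
        close to the RMS acceleration of the 23 Hz, 5 mm oscillation.
        """
        fps, n = 400.0, 240
        t = np.arange(n) / fps
        a, f, noise_sd = 0.005, 23.0, 5e-4
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(5):
            z = 3.0 * t + a * np.sin(2 * np.pi * f * t) \
                + rng.normal(0, noise_sd, n)
            track = Track3D(times=t, positions=np.column_stack(
                [np.zeros(n), np.zeros(n), z]), residuals=np.zeros(n), fps=fps)
            sigma_a = a * (2 * np.pi * f) ** 2 / np.sqrt(2)
            sm = kalman_smooth(track, process_noise=sigma_a,
                               measurement_noise=noise_sd)
            v_sg = savgol_filter(z, window_length=15, polyorder=3, deriv=1,
                                 delta=1 / fps)
            core = slice(10, n - 10)  # both estimators have edge transients
            diff = sm.velocities[core, 2] - v_sg[core]
            ratios.append(np.sqrt(np.mean(diff ** 2))
                          / np.sqrt(np.mean(v_sg[core] ** 2)))
        assert max(ratios) < 0.05


class TestTrajectoryAverageSpeed:
    def test_constant_velocity(self):
        sm = kalman_smooth(linear_track(n=60), 1.0, 1e-4)
        assert trajectory_average_speed(sm) == pytest.approx(3.0, abs=1e-6)

    def test_stationary_track(self):
        sm = kalman_smooth(linear_track(velocity=(0, 0, 0)), 1.0, 1e-4)
        assert trajectory_average_speed(sm) == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_trial_with_bob(self, params, rig, dlts):
        """The wingbeat bob inflates mean speed by at most a few percent."""
        rec = make_recording(params, rig, speed=3.0, freq=23.0, seed=2)
        track = reconstruct_track(rec.pixel_tracks["beak"], dlts, rig.fps)
        sm = kalman_smooth(track)
        assert trajectory_average_speed(sm) == pytest.approx(3.0, rel=0.03)

    def test_net_displacement_variant(self):
        sm = kalman_smooth(linear_track(n=60), 1.0, 1e-4)
        assert trajectory_average_speed(sm, method="net_displacement") == \
            pytest.approx(3.0, abs=1e-6)


class TestWingbeatFrequency:
    @pytest.mark.parametrize("onsets, expected", [
        ([0.0, 0.1, 0.2, 0.3, 0.4], 10.0),
        (np.arange(4) / 23.0, 23.0),
    ])
    def test_known_intervals(self, onsets, expected):
        assert wingbeat_frequency(onsets) == pytest.approx(expected)

    def test_time_origin_invariance(self):
        onsets = np.array([0.01, 0.055, 0.097, 0.141])
        assert wingbeat_frequency(onsets) == pytest.approx(
            wingbeat_frequency(onsets + 3.7))

    def test_frame_quantisation_error_bound(self, params, rig):
        """Onsets quantised to 400 fps frames stay within +/-0.5 Hz of the
        generating frequency."""
        for seed in range(20):
            rec = make_recording(params, rig, speed=3.0, freq=23.1, seed=seed)
            onsets = rec.downstroke_onset_frames / rig.fps
            if len(onsets) >= 2:
                assert wingbeat_frequency(onsets) == pytest.approx(23.1, abs=0.5)

    def test_too_few_onsets_rejected(self):
        with pytest.raises(TrackError):
            wingbeat_frequency([0.1])
        with pytest.raises(TrackError):
            wingbeat_frequency([0.2, 0.1])


class TestMaxWingspan:
    def test_recovers_generator_wingspan(self, video_study):
        cohort = video_study["cohort_frame"].set_index("bird_id")
        measured = video_study["bmax"].set_index("bird_id")
        err = (measured["bmax_m"] - cohort["bmax_m"]).abs()
        assert err.max() < 2e-3

    def test_mirrored_wingtips_double_excursion(self):
        n, fps = 50, 400.0
        t = np.arange(n) / fps
        exc = 0.05 * (0.6 + 0.4 * np.cos(2 * np.pi * 23 * t))
        left = Track3D(times=t, positions=np.column_stack(
            [-exc, np.zeros(n), np.zeros(n)]), residuals=np.zeros(n), fps=fps)
        right = Track3D(times=t, positions=np.column_stack(
            [exc, np.zeros(n), np.zeros(n)]), residuals=np.zeros(n), fps=fps)
        assert max_wingspan(left, right) == pytest.approx(2 * exc.max())

    def test_missing_wingtip_rejected(self):
        left = linear_track(n=20)
        with pytest.raises(TrackError):
            max_wingspan(left, None)

    def test_insufficient_coverage_rejected(self):
        left = linear_track(n=20)
        right = linear_track(n=20)
        with pytest.raises(TrackError, match="wingbeat"):
            max_wingspan(left, right, onset_times=[0.0, 0.3])


class TestEndToEnd:
    def test_noiseless_speed_recovery(self, noisefree_params, rig):
        study = ef.run_study(noisefree_params, seed=3, mode="video")
        truths = truth_by_trial(study)
        fl = study["flights"]
        truth = np.array([truths[i].true_speed for i in fl.trial_id])
        rel = np.abs(fl.mean_speed.to_numpy() - truth) / truth
        assert rel.max() < 1e-3

    def test_default_noise_speed_correlation(self, video_study):
        truths = truth_by_trial(video_study)
        fl = video_study["flights"]
        truth = np.array([truths[i].true_speed for i in fl.trial_id])
        assert np.corrcoef(truth, fl.mean_speed)[0, 1] > 0.99
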