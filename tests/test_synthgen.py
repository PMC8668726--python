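"""Cohort, trial and recording generation: balance, determinism, and
fidelity of the built-in ground-truth dynamics."""

from dataclasses import replace

import numpy as np
import pytest

import escapeflight as ef
from escapeflight.synthgen import (ConfigurationError, GroundTruthParams,
                                   generate_calibration_field, generate_cohort,
                                   simulate_trials, synthesize_trajectory)
from escapeflight.calib import fit_dlt, project


class TestCohort:
    def test_balanced_design(self, params):
        cohort = generate_cohort(params)
        assert len(cohort) == 18
        assert sum(b.sex == "female" for b in cohort) == 9
        assert sum(b.sex == "male" for b in cohort) == 9
        for sex in ("female", "male"):
            tags = sorted(b.tag_mass_g for b in cohort if b.sex == sex)
            assert tags == [0, 0, 0, 0.9, 0.9, 0.9, 1.2, 1.2, 1.2]

    def test_seeded_determinism(self, params):
        assert generate_cohort(params) == generate_cohort(params)

    def test_tag_mass_fraction_matches_field_ratios(self, params):
        """0.9 g on a female is ~6% of body mass on average."""
        ratios = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            for b in generate_cohort(params, rng=rng):
                if b.sex == "female" and b.treatment == "lighter_tag":
                    ratios.append(0.9 / b.body_mass_day1_g)
        assert np.mean(ratios) == pytest.approx(0.063, abs=0.01)

    def test_sexed_disk_loading_means(self, params):
        loadings = {"female": [], "male": []}
        for seed in range(60):
            rng = np.random.default_rng(seed)
            for b in generate_cohort(params, rng=rng):
                loadings[b.sex].append(
                    ef.disk_loading(b.body_mass_day1_g * 1e-3, b.wingspan_bmax_m))
        assert np.mean(loadings["male"]) == pytest.approx(17.7, abs=0.2)
        assert np.mean(loadings["female"]) == pytest.approx(18.0, abs=0.2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GroundTruthParams(birds_per_cell=0).validate()
        with pytest.raises(ConfigurationError):
            GroundTruthParams(residual_sd_speed=-1).validate()


class TestTrials:
    def test_default_schedule(self, params):
        cohort = generate_cohort(params)
        trials = simulate_trials(cohort, params)
        assert len(trials) == 360  # 18 birds x 4 days x 5 flights
        per_bird_day = {}
        for t in trials:
            per_bird_day.setdefault((t.bird_id, t.test_day), 0)
            per_bird_day[(t.bird_id, t.test_day)] += 1
        assert set(per_bird_day.values()) == {5}
        assert {t.test_day for t in trials} == {1, 7, 14, 28}

    def test_noise_free_day_slope_linearity(self, params):
        p = replace(params, residual_sd_speed=0.0, bird_intercept_sd_speed=0.0,
                    residual_sd_freq=0.0, bird_intercept_sd_freq=0.0,
                    mass_drift_frac_per_day=0.0)
        cohort = generate_cohort(p)
        trials = simulate_trials(cohort, p)
        by = {}
        for t in trials:
            by.setdefault((t.bird_id, t.test_day), t)
        for b in cohort:
            slope = p.speed_day_slope_by_treatment[b.treatment]
            d1, d28 = by[(b.bird_id, 1)], by[(b.bird_id, 28)]
            assert d28.true_speed - d1.true_speed == pytest.approx(
                slope * 27, abs=1e-10)
            assert d28.true_freq - d1.true_freq == pytest.approx(
                p.freq_day_slope * 27, abs=1e-10)

    def test_noise_free_ols_recovers_loading_slope(self, params):
        """Shut off every noise source and the day/tag terms: true speed is
        then exactly linear in disk loading with the generator slope."""
        p = replace(params, residual_sd_speed=0.0, bird_intercept_sd_speed=0.0,
                    tag_offset=0.0,
                    speed_day_slope_by_treatment={
                        "control": 0.0, "lighter_tag": 0.0, "heavier_tag": 0.0})
        trials = simulate_trials(generate_cohort(p), p)
        x = np.array([t.loading_real for t in trials])
        y = np.array([t.true_speed for t in trials])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(p.speed_loading_slope, abs=1e-9)

    def test_mass_drift_compounds(self, params):
        cohort = generate_cohort(params)
        trials = simulate_trials(cohort, params)
        mass1 = {t.bird_id: t.body_mass_on_day_g for t in trials if t.test_day == 1}
        for t in trials:
            if t.test_day == 28:
                gain = t.body_mass_on_day_g / mass1[t.bird_id]
                assert gain == pytest.approx(1.0006 ** 27, rel=1e-12)
        assert 1.0006 ** 27 == pytest.approx(1.0163, abs=1e-4)

    def test_effect_size_fidelity_over_replicates(self, params):
        """Mean OLS slope of noise-free true speed on loading across replicate
        cohorts equals the generating slope up to Monte-Carlo error."""
        p = replace(params, residual_sd_speed=0.0, bird_intercept_sd_speed=0.0,
                    tag_offset=0.0,
                    speed_day_slope_by_treatment={
                        "control": 0.0, "lighter_tag": 0.0, "heavier_tag": 0.0})
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            cohort = generate_cohort(p, rng=rng)
            trials = simulate_trials(cohort, p, rng=rng)
            x = np.array([t.loading_real for t in trials])
            y = np.array([t.true_speed for t in trials])
            slopes.append(np.polyfit(x, y, 1)[0])
        assert np.mean(slopes) == pytest.approx(p.speed_loading_slope, abs=1e-6)


class TestTrajectory:
    def make_recording(self, params, rig, speed=3.0, freq=23.0, seed=0):
        p = replace(params, **({} if seed is None else {}))
        cohort = generate_cohort(params)
        bird = cohort[0]
        trial = ef.TrialPlan(trial_id="t", bird_id=bird.bird_id, test_day=1,
                             flight_index=1,
                             body_mass_on_day_g=bird.body_mass_day1_g,
                             loading_real=18.0, true_speed=speed,
                             true_freq=freq)
        return synthesize_trajectory(trial, rig, bird, params,
                                     rng=np.random.default_rng(seed)), bird

    def test_frame_count_covers_focal_section(self, params, rig):
        rec, _ = self.make_recording(params, rig, speed=3.0)
        # 0.4 m at 3 m/s and 400 fps is ~53 frames
        assert 50 <= len(rec.times) <= 57

    def test_downstroke_onset_count(self, params, rig):
        rec, _ = self.make_recording(params, rig, speed=3.0, freq=23.0)
        # ~0.133 s at 23 beats/s: 3-4 onsets, strictly increasing
        assert 3 <= len(rec.downstroke_onset_frames) <= 4
        assert np.all(np.diff(rec.downstroke_onset_frames) > 0)

    def test_noiseless_projection_is_exact(self, noisefree_params, rig):
        rec, _ = self.make_recording(noisefree_params, rig)
        for point, truth in rec.truth_positions.items():
            for ci, cam in enumerate(rig.cameras):
                np.testing.assert_allclose(rec.pixel_tracks[point][ci],
                                           project(cam, truth), atol=1e-9)

    def test_pixels_within_sensor(self, params, rig):
        rec, _ = self.make_recording(params, rig)
        for tracks in rec.pixel_tracks.values():
            assert tracks.min() >= 0
            assert tracks[..., 0].max() <= rig.resolution[0] - 1
            assert tracks[..., 1].max() <= rig.resolution[1] - 1

    def test_seeded_determinism(self, params, rig):
        r1, _ = self.make_recording(params, rig, seed=5)
        r2, _ = self.make_recording(params, rig, seed=5)
        np.testing.assert_array_equal(r1.pixel_tracks["beak"],
                                      r2.pixel_tracks["beak"])
        np.testing.assert_array_equal(r1.downstroke_onset_frames,
                                      r2.downstroke_onset_frames)


class TestCalibrationField:
    def test_too_few_beads_rejected(self, rig):
        with pytest.raises(ConfigurationError, match=">= 6"):
            generate_calibration_field(rig, n_beads=5)

    def test_noiseless_beads_give_exact_dlt(self, rig):
        field = generate_calibration_field(rig, n_beads=30, seed=3)
        for ci in range(len(rig.cameras)):
            dlt = fit_dlt(field.positions, field.pixels[ci])
            assert dlt.reprojection_rmse < 1e-9

    def test_beads_span_focal_volume(self, rig):
        field = generate_calibration_field(rig, n_beads=200, seed=4)
        assert np.all(field.positions.min(axis=0) < rig.focal_lo + 0.05)
        assert np.all(field.positions.max(axis=0) > rig.focal_hi - 0.05)
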