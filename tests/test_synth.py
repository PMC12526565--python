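"""Simulator contracts: stream sizes, determinism, cue structure."""

import numpy as np
import pytest

from nightfall.synth import (ADL_KINDS, FALL_KINDS, ActivityScript, NoiseConfig,
                             TemplateConfig, generate_cohort, generate_trial)


class TestActivityScript:
    def test_fall_requires_event_interval(self):
        with pytest.raises(ValueError):
            ActivityScript(activity_kind="fall_forward", duration=10.0)

    def test_adl_rejects_event_interval(self):
        with pytest.raises(ValueError):
            ActivityScript(activity_kind="walk", duration=10.0,
                           event_interval=(1.0, 2.0))

    def test_event_interval_must_fit_duration(self):
        with pytest.raises(ValueError):
            ActivityScript(activity_kind="fall_lateral", duration=5.0,
                           event_interval=(4.0, 6.0))

    def test_minimum_duration(self):
        with pytest.raises(ValueError):
            ActivityScript(activity_kind="walk", duration=1.0)


class TestGenerateTrial:
    def test_nominal_stream_lengths_at_zero_jitter(self):
        script = ActivityScript("fall_forward", duration=120.0,
                                event_interval=(50.0, 52.0))
        rec = generate_trial(script, NoiseConfig.zero(), seed=1)
        assert len(rec.imu) == 120 * 50 == 6000
        assert len(rec.pose) == 120 * 30 == 3600

    def test_walk_has_no_fall_label_and_respects_cap(self):
        script = ActivityScript("walk", duration=10.0)
        tpl = TemplateConfig()
        rec = generate_trial(script, NoiseConfig.zero(), seed=2, template=tpl)
        assert rec.ground_truth.sum() == 0
        mag = np.linalg.norm(rec.imu[:, :3], axis=1)
        assert mag.max() <= tpl.adl_accel_cap_g + 1e-9

    def test_fall_peak_matches_configured_template_peak(self):
        """Brute-force scan: with unit impulse multiplier and zero noise the
        max acceleration magnitude inside the event equals the template peak."""
        tpl = TemplateConfig(fall_impulse_peak_g=3.7)
        script = ActivityScript("fall_lateral", duration=20.0,
                                event_interval=(8.0, 9.6),
                                subject_params={"impulse_scale": 1.0})
        rec = generate_trial(script, NoiseConfig.zero(), seed=3, template=tpl)
        e0, e1 = script.event_interval
        in_event = (rec.imu_t >= e0) & (rec.imu_t <= e1)
        mag = np.linalg.norm(rec.imu[in_event, :3], axis=1)
        assert mag.max() == pytest.approx(3.7, abs=1e-9)

    def test_determinism(self):
        script = ActivityScript("fall_backward", duration=8.0,
                                event_interval=(3.0, 4.5))
        a = generate_trial(script, NoiseConfig(), seed=9)
        b = generate_trial(script, NoiseConfig(), seed=9)
        assert np.array_equal(a.imu, b.imu)
        assert np.array_equal(a.pose, b.pose)
        assert np.array_equal(a.imu_t, b.imu_t)

    def test_event_too_close_to_end_rejected(self):
        script = ActivityScript("fall_forward", duration=4.0,
                                event_interval=(3.9, 4.0))
        with pytest.raises(ValueError, match="too short"):
            generate_trial(script, seed=0)

    def test_sensor_range_invariants(self):
        for kind in FALL_KINDS + ADL_KINDS:
            ev = (4.0, 5.5) if kind in FALL_KINDS else None
            script = ActivityScript(kind, duration=10.0, event_interval=ev)
            rec = generate_trial(script, NoiseConfig(), seed=7)
            assert np.abs(rec.imu[:, :3]).max() <= 16.0
            assert np.abs(rec.imu[:, 3:]).max() <= 2000.0
            assert rec.pose.min() >= 0.0 and rec.pose.max() <= 1.0

    def test_clock_offset_bounded(self):
        script = ActivityScript("walk", duration=6.0)
        noise = NoiseConfig(clock_offset_max_s=0.1, sample_jitter_sd_s=0.0)
        rec = generate_trial(script, noise, seed=5)
        assert abs(rec.imu_t[0]) <= 0.1
        assert abs(rec.pose_t[0]) <= 0.1
        assert np.all(np.diff(rec.imu_t) > 0)


class TestGenerateCohort:
    def test_default_balance_and_counts(self):
        cohort = generate_cohort(4, 10, seed=0, duration=8.0)
        trials = cohort.all_trials()
        assert len(trials) == 40
        falls = [t for t in trials if t.script.is_fall]
        assert len(falls) == 20

    def test_minimal_cohort(self):
        cohort = generate_cohort(2, 2, seed=0, duration=8.0)
        assert len(cohort.subjects) == 2
        assert all(len(cohort.trials[s]) == 2 for s in cohort.subjects)

    def test_same_seed_identical(self):
        a = generate_cohort(2, 2, seed=3, duration=6.0)
        b = generate_cohort(2, 2, seed=3, duration=6.0)
        for s in a.subjects:
            for ta, tb in zip(a.trials[s], b.trials[s]):
                assert np.array_equal(ta.imu, tb.imu)
                assert np.array_equal(ta.pose, tb.pose)

    def test_subject_params_shared_within_subject(self):
        cohort = generate_cohort(2, 4, seed=1, duration=6.0)
        for s in cohort.subjects:
            params = [t.script.subject_params for t in cohort.trials[s]]
            assert all(p == params[0] for p in params)

    def test_odd_split_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, 3, seed=0, duration=6.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, 2, seed=0)


class TestCueStructure:
    def test_fall_peak_acceleration_exceeds_adl(self, small_cohort):
        """Separation property: mean peak |a| over fall trials strictly
        exceeds that over ADL trials."""
        peaks = {True: [], False: []}
        for t in small_cohort.all_trials():
            mag = np.linalg.norm(t.imu[:, :3], axis=1)
            peaks[t.script.is_fall].append(mag.max())
        assert np.mean(peaks[True]) > np.mean(peaks[False])

    def test_postural_cue_after_fall_and_absent_while_walking(self):
        from nightfall.evaluate import _flags_from_array
        from nightfall.vision import PRONE, streak_membership
        script = ActivityScript("fall_forward", duration=20.0,
                                event_interval=(8.0, 9.5))
        rec = generate_trial(script, NoiseConfig.zero(), seed=4)
        flags = _flags_from_array(rec.pose, 0.5)
        post_event = flags[int(9.5 * 30):]
        member = streak_membership(post_event, required=30)
        assert member.any()
        walk = generate_trial(ActivityScript("walk", duration=20.0),
                              NoiseConfig.zero(), seed=4)
        assert not (_flags_from_array(walk.pose, 0.5) == PRONE).any()
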