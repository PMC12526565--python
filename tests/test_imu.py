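"""IMU branch: filtering, windowing, reconstruction error, tau calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from nightfall.imu import (AnomalyThreshold, ImuWindow, LstmAutoencoder,
                           anomaly_score, calibrate_tau, is_abnormal,
                           make_windows, preprocess, reconstruction_mse)


def six_channel(x):
    return np.tile(np.asarray(x, dtype=float)[:, None], (1, 6))


class TestPreprocess:
    def test_constant_input_maps_to_zero(self):
        # DC lies outside the 0.2-20 Hz pass band; with identity z-score
        # statistics the output is the filtered signal, which is ~0 everywhere
        x = six_channel(np.ones(2000))
        out = preprocess(x, stats=(np.zeros(6), np.ones(6)))
        assert np.abs(out).max() < 1e-6

    def test_low_frequency_attenuated_relative_to_passband(self):
        """The 0.05 Hz component must be attenuated >10x more than 5 Hz,
        matching the designed Butterworth magnitude response."""
        n = 50 * 120
        t = np.arange(n) / 50.0
        lo = six_channel(np.sin(2 * np.pi * 0.05 * t))
        hi = six_channel(np.sin(2 * np.pi * 5.0 * t))
        sos = signal.butter(4, (0.2, 20.0), btype="bandpass", fs=50.0,
                            output="sos")
        lo_f = signal.sosfiltfilt(sos, lo, axis=0)
        hi_f = signal.sosfiltfilt(sos, hi, axis=0)
        core = slice(n // 4, 3 * n // 4)   # avoid edge transients
        gain_lo = np.abs(lo_f[core, 0]).max()
        gain_hi = np.abs(hi_f[core, 0]).max()
        assert gain_hi > 10 * gain_lo
        # and the independently evaluated frequency response agrees
        w, h = signal.sosfreqz(sos, worN=[0.05, 5.0], fs=50.0)
        assert np.abs(h[1]) ** 2 > 10 * np.abs(h[0]) ** 2  # zero-phase doubles

    def test_self_normalized_moments(self, rng):
        x = rng.standard_normal((100_000, 6))
        out = preprocess(x)
        assert np.all(np.abs(out.mean(axis=0)) < 0.01)
        assert np.allclose(out.std(axis=0), 1.0, atol=0.01)

    def test_training_stats_reused(self, rng):
        x = rng.standard_normal((3000, 6))
        mean = 0.1 * np.ones(6)
        sd = 2.0 * np.ones(6)
        out = preprocess(x, stats=(mean, sd))
        # the supplied statistics, not the series' own moments, normalize
        identity = preprocess(x, stats=(np.zeros(6), np.ones(6)))
        assert np.allclose(out, (identity - mean) / sd)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            preprocess(np.zeros((10, 6)))

    def test_zero_variance_channel_rejected(self, rng):
        x = rng.standard_normal((500, 6))
        stats = (np.zeros(6), np.array([1, 1, 0, 1, 1, 1.0]))
        with pytest.raises(ValueError, match="channel 2"):
            preprocess(x, stats=stats)

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess(rng.standard_normal((500, 6)), band=(0.2, 30.0))


class TestMakeWindows:
    @pytest.mark.parametrize("n,expected", [(60, 1), (150, 4), (59, 0),
                                            (0, 0), (90, 2), (120, 3)])
    def test_window_counts(self, n, expected, rng):
        wins = make_windows(rng.standard_normal((n, 6)))
        assert len(wins) == expected
        if wins:
            assert [w.index for w in wins] == list(range(expected))

    def test_starts_at_multiples_of_step(self, rng):
        x = rng.standard_normal((150, 6))
        wins = make_windows(x)
        for k, w in enumerate(wins):
            assert np.array_equal(w.samples, x[30 * k:30 * k + 60])

    @given(n=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_count_formula_matches_enumeration(self, n):
        # enumeration oracle: all starts s = 30k with s + 60 <= n
        expected = len([s for s in range(0, max(n - 59, 0), 30)])
        series = np.zeros((n, 6))
        assert len(make_windows(series)) == expected

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_windows(np.zeros((100, 6)), window=1)
        with pytest.raises(ValueError):
            make_windows(np.zeros((100, 6)), overlap=1.0)


class TestReconstructionMse:
    def test_identical_input_gives_zero(self, rng):
        x = rng.standard_normal((60, 6))
        assert reconstruction_mse(x, x) == 0.0

    def test_unit_residual_gives_six(self):
        x = np.zeros((60, 6))
        assert reconstruction_mse(x, x + 1.0) == pytest.approx(6.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((60, 6))
        xhat = rng.standard_normal((60, 6))
        total = 0.0
        for t in range(60):
            for c in range(6):
                total += (x[t, c] - xhat[t, c]) ** 2
        assert reconstruction_mse(x, xhat) == pytest.approx(total / 60)

    def test_sign_symmetric(self, rng):
        x = rng.standard_normal((60, 6))
        r = rng.standard_normal((60, 6))
        assert reconstruction_mse(x, x + r) == pytest.approx(
            reconstruction_mse(x, x - r))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_mse(np.zeros((60, 6)), np.zeros((30, 6)))


class TestCalibrateTau:
    def test_linear_interpolation_convention(self):
        errors = np.arange(1.0, 101.0)
        thr = calibrate_tau(errors, 95.0)
        assert thr.tau == pytest.approx(95.05)

    def test_constant_errors(self):
        thr = calibrate_tau(np.full(30, 2.5))
        assert thr.tau == 2.5

    def test_percentile_100_is_max(self, rng):
        e = rng.uniform(0.1, 5.0, 50)
        assert calibrate_tau(e, 100.0).tau == pytest.approx(e.max())

    def test_small_sample_flagged_degraded(self):
        thr = calibrate_tau(np.linspace(0.1, 1, 10))
        assert thr.degraded

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_tau(np.array([]))

    @given(p1=st.floats(1, 99), p2=st.floats(1, 99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_percentile(self, p1, p2):
        e = np.linspace(0.5, 3.0, 40)
        lo, hi = sorted([p1, p2])
        assert calibrate_tau(e, lo).tau <= calibrate_tau(e, hi).tau + 1e-12


class TestAnomalyScore:
    def test_zero_mse_scores_zero(self):
        assert anomaly_score(0.0, 2.0) == 0.0

    def test_clamped_at_one(self):
        assert anomaly_score(4.0, 2.0) == 1.0

    def test_half_tau_scores_half(self):
        assert anomaly_score(1.0, 2.0) == 0.5

    def test_abnormal_flag_is_strict(self):
        assert not is_abnormal(2.0, 2.0)
        assert is_abnormal(2.0 + 1e-12, 2.0)

    @given(mse=st.floats(0, 10), tau=st.floats(0.01, 10),
           k=st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_scale_invariant(self, mse, tau, k):
        s = anomaly_score(mse, tau)
        assert 0.0 <= s <= 1.0
        assert anomaly_score(k * mse, k * tau) == pytest.approx(s)
        assert anomaly_score(mse * 1.01, tau) >= s - 1e-12

    def test_negative_mse_rejected(self):
        with pytest.raises(ValueError):
            anomaly_score(-0.1, 1.0)

    def test_score_saturates_at_tau(self):
        thr = AnomalyThreshold(tau=0.5, percentile=95,
                               calibration_errors=np.ones(20))
        assert anomaly_score(0.5, thr) == 1.0


class TestLstmAutoencoderEstimator:
    def test_sklearn_params_roundtrip(self):
        est = LstmAutoencoder(hidden_sizes=(8,), epochs=2)
        params = est.get_params()
        est2 = LstmAutoencoder(**params)
        assert est2.get_params() == params

    def test_separates_fall_windows_after_adl_training(self, small_cohort):
        """Autoencoder trained on ADL windows reconstructs held-out ADL
        windows better than fall-event windows (fixed seed)."""
        from nightfall.evaluate import PipelineConfig, _window_data
        from nightfall.imu import filter_stats
        cfg = PipelineConfig.small()
        trials = small_cohort.all_trials()
        stats = filter_stats([t.imu for t in trials])
        Xn, Xf = [], []
        for t in trials:
            X, _, y = _window_data(t, stats, cfg)
            Xn.append(X[y == 0])
            Xf.append(X[y == 1])
        Xn = np.concatenate(Xn)
        Xf = np.concatenate(Xf)
        est = LstmAutoencoder(hidden_sizes=(16,), epochs=8, patience=8,
                              random_state=0)
        est.fit(Xn[:300])
        held_out_normal = est.score_samples(Xn[300:500])
        fall_scores = est.score_samples(Xf)
        assert fall_scores.mean() > held_out_normal.mean()
        assert np.median(est.anomaly_scores(Xf)) > np.median(
            np.minimum(held_out_normal / est.tau_, 1.0))

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            LstmAutoencoder(hidden_sizes=(8,)).fit(np.empty((0, 60, 6)))

    def test_fit_is_deterministic(self, rng):
        X = rng.standard_normal((40, 60, 6)) * 0.3
        taus = [LstmAutoencoder(hidden_sizes=(8,), epochs=2, patience=2,
                                random_state=5).fit(X).tau_
                for _ in range(2)]
        assert taus[0] == taus[1]
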