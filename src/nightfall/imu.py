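"""IMU branch: preprocessing, windowing, LSTM-autoencoder anomaly scoring.

The inertial stream is band-pass filtered (4th-order Butterworth, zero-phase
forward-backward application, 0.2-20 Hz at 50 Hz sampling) and z-scored per
channel, segmented into 60-sample windows with 50% overlap (1.2 s at 50 Hz),
and scored by the reconstruction error of an LSTM autoencoder trained on
non-fall motion only.  A window's error is

    MSE(n) = (1/T) * sum_t || x_n(t) - xhat_n(t) ||^2,   T = 60,

with the squared Euclidean norm taken over the six channels.  The anomaly
threshold tau is a high percentile (default 95th, linear interpolation
convention) of the training reconstruction errors, and the bounded anomaly
score used by the fusion stage is  s_anomaly = min(MSE / tau, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .nn import LstmAutoencoderNet, TrainRecipe, fit_autoencoder

__all__ = [
    "ImuWindow",
    "AnomalyThreshold",
    "preprocess",
    "make_windows",
    "reconstruction_mse",
    "calibrate_tau",
    "anomaly_score",
    "LstmAutoencoder",
]

SAMPLING_RATE_HZ = 50.0
WINDOW_SAMPLES = 60
WINDOW_OVERLAP = 0.5


@dataclass(frozen=True)
class ImuWindow:
    """One preprocessed 60x6 inertial segment."""

    index: int
    samples: np.ndarray              # (60, 6)
    interval: tuple[float, float]    # (start, end) seconds

    def __post_init__(self):
        if self.samples.shape != (WINDOW_SAMPLES, 6):
            raise ValueError(f"window must be {WINDOW_SAMPLES}x6")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite values")

    @property
    def center(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass(frozen=True)
class AnomalyThreshold:
    """Calibrated anomaly threshold with its provenance."""

    tau: float
    percentile: float
    calibration_errors: np.ndarray = field(repr=False)
    degraded: bool = False  # calibrated from fewer than 20 errors

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def preprocess(series: np.ndarray, band: tuple[float, float] = (0.2, 20.0),
               fs: float = SAMPLING_RATE_HZ, order: int = 4,
               stats: tuple[np.ndarray, np.ndarray] | None = None
               ) -> np.ndarray:
    """Band-pass filter then z-score a (N, 6) inertial series.

    Filtering is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``), so the result is zero-phase and the effective order
    doubles.  Z-scoring uses ``stats = (mean, sd)`` when given (training
    statistics reused at test time) and the series' own moments otherwise.
    Filtering comes first: filtering after normalization would re-introduce
    a nonzero mean.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[1] != 6:
        raise ValueError("series must be (N, 6)")
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs} (Nyquist {fs / 2})")
    min_len = 3 * (2 * order + 1)  # forward-backward warm-up
    if len(series) < min_len:
        raise ValueError(f"series too short for zero-phase filtering "
                         f"(need >= {min_len} samples, got {len(series)})")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series, axis=0)
    if stats is not None:
        mean, sd = (np.asarray(a, dtype=np.float64) for a in stats)
    else:
        mean = filtered.mean(axis=0)
        sd = filtered.std(axis=0)
    if np.any(sd == 0):
        ch = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance channel {ch}; cannot z-score")
    return (filtered - mean) / sd


def filter_stats(series_list: list[np.ndarray],
                 band: tuple[float, float] = (0.2, 20.0),
                 fs: float = SAMPLING_RATE_HZ, order: int = 4
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/sd of the band-passed concatenation of training
    series, for leakage-free normalization of held-out data."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    parts = [signal.sosfiltfilt(sos, np.asarray(s, dtype=np.float64), axis=0)
             for s in series_list]
    cat = np.concatenate(parts, axis=0)
    return cat.mean(axis=0), cat.std(axis=0)


def make_windows(series: np.ndarray, t: np.ndarray | None = None,
                 window: int = WINDOW_SAMPLES,
                 overlap: float = WINDOW_OVERLAP) -> list[ImuWindow]:
    """Segment a (N, 6) series into full windows with the given overlap.

    Starts fall at 0, step = window * (1 - overlap); incomplete trailing
    windows are dropped.  N < window gives an empty list.
    """
    series = np.asarray(series, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(window * (1 - overlap))))
    n = len(series)
    out = []
    for i, start in enumerate(range(0, n - window + 1, step)):
        seg = series[start:start + window]
        if t is not None:
            interval = (float(t[start]), float(t[start + window - 1]))
        else:
            interval = (start / SAMPLING_RATE_HZ,
                        (start + window - 1) / SAMPLING_RATE_HZ)
        out.append(ImuWindow(index=i, samples=seg, interval=interval))
    return out


def reconstruction_mse(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean over timesteps of the squared Euclidean channel residual."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    r = x - xhat
    return float(np.mean(np.sum(r * r, axis=-1), axis=-1))


def calibrate_tau(errors: np.ndarray, percentile: float = 95.0) -> AnomalyThreshold:
    """Percentile of the training reconstruction errors (linear
    interpolation between order statistics).  Fewer than 20 values flags the
    calibration as degraded; an empty sample is rejected."""
    errors = np.asarray(errors, dtype=np.float64).ravel()
    if errors.size == 0:
        raise ValueError("cannot calibrate tau from an empty error sample")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    tau = float(np.percentile(errors, percentile, method="linear"))
    return AnomalyThreshold(tau=tau, percentile=percentile,
                            calibration_errors=errors.copy(),
                            degraded=errors.size < 20)


def anomaly_score(mse: float, threshold: AnomalyThreshold | float) -> float:
    """Bounded anomaly score min(MSE / tau, 1)."""
    tau = threshold.tau if isinstance(threshold, AnomalyThreshold) else float(threshold)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if mse < 0:
        raise ValueError("mse must be nonnegative")
    return min(mse / tau, 1.0)


def is_abnormal(mse: float, threshold: AnomalyThreshold | float) -> bool:
    """Binary abnormality flag: MSE strictly above tau."""
    tau = threshold.tau if isinstance(threshold, AnomalyThreshold) else float(threshold)
    return mse > tau


class LstmAutoencoder(BaseEstimator):
    """Unsupervised inertial anomaly detector (sklearn-style estimator).

    Fit on preprocessed non-fall windows of shape (n_windows, 60, 6); the
    anomaly threshold ``tau_`` is calibrated as the ``tau_percentile``-th
    percentile of the training reconstruction errors.

    Parameters
    ----------
    hidden_sizes : stacked encoder LSTM widths (decoder mirrors them); the
        study architecture is (128, 128) giving a 256-dim latent.
    tau_percentile : calibration percentile for tau (default 95).
    lr, batch_size, epochs, patience : Adam/early-stopping recipe
        (study recipe: 1e-3, 32, 50, 10).
    random_state : seed for initialization, batching and the validation split.

    Attributes
    ----------
    net_ : the trained :class:`~nightfall.nn.LstmAutoencoderNet`.
    training_errors_ : per-window reconstruction MSE on the training set.
    threshold_ : calibrated :class:`AnomalyThreshold`; ``tau_`` its value.
    history_ : per-epoch train/validation loss records.
    """

    def __init__(self, hidden_sizes=(128, 128), tau_percentile=95.0,
                 lr=1e-3, batch_size=32, epochs=50, patience=10,
                 val_frac=0.15, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.tau_percentile = tau_percentile
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_frac = val_frac
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate(X)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.net_ = LstmAutoencoderNet(n_channels=6,
                                       hidden_sizes=tuple(self.hidden_sizes),
                                       seed=self.random_state)
        recipe = TrainRecipe(lr=self.lr, batch_size=self.batch_size,
                             epochs=self.epochs, patience=self.patience,
                             val_frac=self.val_frac)
        info = fit_autoencoder(self.net_, X, recipe, seed=self.random_state)
        self.history_ = info["history"]
        self.n_parameters_ = self.net_.n_parameters()
        self.training_errors_ = self.score_samples(X)
        self.threshold_ = calibrate_tau(self.training_errors_, self.tau_percentile)
        self.tau_ = self.threshold_.tau
        return self

    def score_samples(self, X) -> np.ndarray:
        """Reconstruction MSE per window (higher = more anomalous)."""
        X = self._validate(X)
        out = np.empty(len(X))
        for lo in range(0, len(X), 256):
            xb = X[lo:lo + 256]
            xhat = self.net_.reconstruct(xb)
            r = xb - xhat
            out[lo:lo + 256] = np.mean(np.sum(r * r, axis=2), axis=1)
        return out

    def anomaly_scores(self, X) -> np.ndarray:
        """Bounded fusion scores min(MSE / tau, 1) per window."""
        mse = self.score_samples(X)
        return np.minimum(mse / self.tau_, 1.0)

    def predict(self, X) -> np.ndarray:
        """Binary abnormality flags (MSE strictly above tau)."""
        return (self.score_samples(X) > self.tau_).astype(int)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != WINDOW_SAMPLES or X.shape[2] != 6:
            raise ValueError(f"X must be (n, {WINDOW_SAMPLES}, 6), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X
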