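"""Decision-level fusion of the vision and inertial scores.

The rule compares both branch scores with a common threshold alpha = 0.70
(strict inequalities):

* FALL            when p_fall > alpha and s_anomaly > alpha,
* LOW_CONFIDENCE  when exactly one of the two exceeds alpha,
* NORMAL          otherwise.

For few-shot personalization a small trainable head maps
(p_fall, s_anomaly) to a fall probability.  Its hidden units are steep
threshold gates h_j = sigmoid(kappa * (w_j . x - theta_j)); at initialization
two gate units sit exactly at alpha on each input so the head reproduces the
AND rule away from the threshold, and because the unit thresholds theta_j are
explicit parameters multiplied by the fixed steepness kappa, a handful of
small gradient steps (SGD, learning rate 1e-4, 50 iterations) can move the
decision boundary far enough to adapt to a new subject while the two branch
encoders stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "FALL", "LOW_CONFIDENCE", "NORMAL",
    "FusionConfig", "FusionDecision",
    "fuse", "align_epochs", "FusionHead", "fine_tune_head",
]

FALL = "FALL"
LOW_CONFIDENCE = "LOW_CONFIDENCE"
NORMAL = "NORMAL"


@dataclass(frozen=True)
class FusionConfig:
    """Common decision threshold and epoch length."""

    alpha: float = 0.70
    p_thresh: float | None = None   # vision threshold; defaults to alpha
    epoch_s: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def vision_threshold(self) -> float:
        return self.alpha if self.p_thresh is None else self.p_thresh


@dataclass(frozen=True)
class FusionDecision:
    p_fall: float | None
    s_anomaly: float | None
    label: str
    epoch: tuple[float, float] | None = None


def fuse(p_fall: float | None, s_anomaly: float | None,
         config: FusionConfig | None = None,
         epoch: tuple[float, float] | None = None) -> FusionDecision:
    """Apply the conjunctive fusion rule to one epoch's scores.

    A missing score (None) counts as not exceeding its threshold, so an
    epoch with a missing modality can never be labeled FALL.
    """
    config = config or FusionConfig()
    for s, nm in ((p_fall, "p_fall"), (s_anomaly, "s_anomaly")):
        if s is not None and not 0.0 <= s <= 1.0:
            raise ValueError(f"{nm}={s} outside [0, 1]")
    v = p_fall is not None and p_fall > config.vision_threshold
    a = s_anomaly is not None and s_anomaly > config.alpha
    if v and a:
        label = FALL
    elif v or a:
        label = LOW_CONFIDENCE
    else:
        label = NORMAL
    return FusionDecision(p_fall=p_fall, s_anomaly=s_anomaly, label=label,
                          epoch=epoch)


def align_epochs(segment_centers: np.ndarray, imu_centers: np.ndarray,
                 imu_scores: np.ndarray, tolerance_s: float = 0.6
                 ) -> list[float | None]:
    """Pair each 1-s vision segment with an IMU anomaly score.

    For every segment center, the paired score is the maximum anomaly score
    among IMU windows whose centers fall within ±``tolerance_s``; None marks
    a segment with no IMU window in range (the pairing stays total).
    """
    segment_centers = np.asarray(segment_centers, dtype=np.float64)
    imu_centers = np.asarray(imu_centers, dtype=np.float64)
    imu_scores = np.asarray(imu_scores, dtype=np.float64)
    if imu_centers.shape != imu_scores.shape:
        raise ValueError("imu_centers and imu_scores must align")
    out: list[float | None] = []
    for c in segment_centers:
        near = np.abs(imu_centers - c) <= tolerance_s
        out.append(float(imu_scores[near].max()) if near.any() else None)
    return out


class FusionHead(BaseEstimator, ClassifierMixin):
    """Trainable two-input fusion head (threshold-gate parameterization).

    ``predict_proba`` on (p_fall, s_anomaly) pairs returns a fall
    probability; the default initialization reproduces the thresholded AND
    rule for scores at least 0.05 away from alpha.  Fine-tuning uses plain
    SGD at the personalization recipe (lr 1e-4, 50 full-batch iterations)
    on binary cross-entropy; total parameter count stays far below 5000.

    Parameters
    ----------
    alpha : decision threshold the gate units are initialized at.
    n_hidden : hidden gate units (the first two implement the AND rule, the
        rest start near zero and give fine-tuning extra capacity).
    kappa : fixed gate steepness.
    gain : output weight of the two rule units.
    """

    def __init__(self, alpha=0.70, n_hidden=16, kappa=25.0, gain=8.0,
                 random_state=0):
        self.alpha = alpha
        self.n_hidden = n_hidden
        self.kappa = kappa
        self.gain = gain
        self.random_state = random_state
        self._init_params()

    def _init_params(self):
        rng = np.random.default_rng(self.random_state)
        nh = self.n_hidden
        self.w_ = rng.normal(0.0, 0.01, size=(nh, 2))
        self.theta_ = rng.normal(0.5, 0.05, size=nh)
        self.v_ = rng.normal(0.0, 0.01, size=nh)
        self.w_[0] = (1.0, 0.0)
        self.w_[1] = (0.0, 1.0)
        self.theta_[0] = self.theta_[1] = self.alpha
        self.v_[0] = self.v_[1] = self.gain
        # output bias at the midpoint between the worst both-pass and the
        # best one-pass gate sums, evaluated 0.05 away from alpha, so the
        # untuned head matches the AND rule outside that band
        s = 1.0 / (1.0 + np.exp(-self.kappa * 0.05))
        self.c_ = -self.gain * 0.5 * (2.0 * s + (1.0 + (1.0 - s)))

    @property
    def n_parameters_(self) -> int:
        return self.w_.size + self.theta_.size + self.v_.size + 1

    def copy(self) -> "FusionHead":
        other = FusionHead(self.alpha, self.n_hidden, self.kappa, self.gain,
                           self.random_state)
        other.w_ = self.w_.copy()
        other.theta_ = self.theta_.copy()
        other.v_ = self.v_.copy()
        other.c_ = float(self.c_)
        return other

    # -- forward --------------------------------------------------------------
    def _forward(self, X: np.ndarray):
        z = self.kappa * (X @ self.w_.T - self.theta_)   # (n, nh)
        h = 1.0 / (1.0 + np.exp(-z))
        logit = h @ self.v_ + self.c_
        return h, logit

    def decision_function(self, X) -> np.ndarray:
        X = self._validate(X)
        return self._forward(X)[1]

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.stack([1.0 - p1, p1], axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def fit(self, X, y, lr: float = 1e-4, n_iter: int = 50):
        """Alias for :func:`fine_tune_head` applied in place."""
        fine_tune_head(self, X, y, lr=lr, n_iter=n_iter, inplace=True)
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (p_fall, s_anomaly)")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("scores must lie in [0, 1]")
        return X


def fine_tune_head(head: FusionHead, X, y, lr: float = 1e-4, n_iter: int = 50,
                   inplace: bool = False) -> FusionHead:
    """Few-shot adaptation: exactly ``n_iter`` full-batch SGD steps on binary
    cross-entropy (early stop only when the loss is exactly zero).  The
    branch encoders are untouched by construction — only the head's
    parameters move."""
    X = FusionHead._validate(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(X) == 0:
        raise ValueError("empty calibration set")
    if len(X) != len(y):
        raise ValueError("X and y must align")
    out = head if inplace else head.copy()
    for _ in range(n_iter):
        h, logit = out._forward(X)
        p = 1.0 / (1.0 + np.exp(-logit))
        # sum-reduction BCE: each additional calibration example adds
        # gradient mass, so adaptation strength grows with K and saturates
        # once the examples are confidently classified
        err = p - y                                    # dBCE/dlogit per item
        if np.max(np.abs(p - y)) == 0.0:
            break
        gv = h.T @ err
        gc = err.sum()
        dh = np.outer(err, out.v_) * h * (1.0 - h) * out.kappa   # (n, nh)
        gw = dh.T @ X
        gtheta = -dh.sum(axis=0)
        out.v_ -= lr * gv
        out.c_ -= lr * gc
        out.w_ -= lr * gw
        out.theta_ -= lr * gtheta
    return out
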