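"""Vision branch: landmark geometry, prone-streak voting, pose Transformer.

Per frame, the 33 normalized landmarks are converted to pixel coordinates,
the landmarks with visibility strictly above a threshold (default 0.5) define
a bounding box, and the box aspect ratio rho = width / height gives a coarse
posture cue: rho > 1 (strictly) flags a prone/horizontal body, rho < 1 an
upright one.  A fall is posture-confirmed only after 30 strictly adjacent
prone frames (1 s at 30 fps); occluded or upright frames reset the run.

For fine-grained temporal analysis, non-overlapping 30-frame segments
(30 x 66 feature matrices: 33 landmarks x 2 coordinates) are classified by a
Transformer encoder; the per-segment vision fall probability is the
Transformer's fallen-class probability, optionally gated by the prone-streak
confirmation (default: multiplied by 0.5 when no confirmation intersects the
segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import TrainRecipe, TransformerClassifierNet, fit_classifier

__all__ = [
    "LandmarkFrame",
    "BoundingBox",
    "PoseSegment",
    "VisionOutput",
    "to_pixels",
    "bounding_box",
    "aspect_ratio",
    "frame_posture_flags",
    "prone_streak",
    "streak_membership",
    "make_segments",
    "PoseTransformer",
    "vision_probability",
]

N_LANDMARKS = 33
FRAMES_PER_SEGMENT = 30
FEATURE_DIM = 2 * N_LANDMARKS  # 66
POSE_FPS = 30.0

PRONE, UPRIGHT, OCCLUDED = 1, 0, -1


@dataclass(frozen=True)
class LandmarkFrame:
    """One frame's 33 landmarks: (x_norm, y_norm, visibility) each."""

    timestamp: float
    landmarks: np.ndarray           # (33, 3)
    frame_dims: tuple[int, int] = (1920, 1080)

    def __post_init__(self):
        lm = np.asarray(self.landmarks, dtype=np.float64)
        if lm.shape != (N_LANDMARKS, 3):
            raise ValueError(f"expected ({N_LANDMARKS}, 3) landmarks, got {lm.shape}")
        if not np.all(np.isfinite(lm)):
            raise ValueError("non-finite landmark values")
        if lm.min() < 0.0 or lm.max() > 1.0:
            raise ValueError("landmark values must lie in [0, 1]")
        object.__setattr__(self, "landmarks", lm)


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_visible: int

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class PoseSegment:
    """30 consecutive frames flattened to a 30 x 66 feature matrix."""

    features: np.ndarray            # (30, 66)
    interval: tuple[float, float]   # (start, end) seconds
    label: int | None = None        # 1 = fallen, 0 = normal

    def __post_init__(self):
        f = np.asarray(self.features, dtype=np.float64)
        if f.shape != (FRAMES_PER_SEGMENT, FEATURE_DIM):
            raise ValueError(f"features must be {FRAMES_PER_SEGMENT}x{FEATURE_DIM}")
        object.__setattr__(self, "features", f)

    @property
    def center(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass(frozen=True)
class VisionOutput:
    """Per-segment vision decision: fall probability + posture confirmation."""

    p_fall: float
    prone_confirmed: bool
    streak_length: int


def to_pixels(x_norm: float, y_norm: float, w_frame: float, h_frame: float
              ) -> tuple[float, float]:
    """Normalized -> pixel coordinates (kept real-valued, no rounding)."""
    if w_frame <= 0 or h_frame <= 0:
        raise ValueError("frame dimensions must be positive")
    return x_norm * w_frame, y_norm * h_frame


def bounding_box(frame: LandmarkFrame, visibility_threshold: float = 0.5
                 ) -> BoundingBox | None:
    """Min/max pixel box over landmarks with visibility strictly above the
    threshold; None (occluded) when fewer than two landmarks qualify."""
    lm = frame.landmarks
    keep = lm[:, 2] > visibility_threshold
    if keep.sum() < 2:
        return None
    w, h = frame.frame_dims
    xs = lm[keep, 0] * w
    ys = lm[keep, 1] * h
    return BoundingBox(x_min=float(xs.min()), x_max=float(xs.max()),
                       y_min=float(ys.min()), y_max=float(ys.max()),
                       n_visible=int(keep.sum()))


def aspect_ratio(box: BoundingBox) -> tuple[float, bool] | None:
    """(rho, prone?) with rho = width / height; prone iff rho > 1 strictly.
    None when the box height is zero (posture undefined)."""
    if box.height <= 0.0:
        return None
    rho = box.width / box.height
    return rho, rho > 1.0


def frame_posture_flags(frames: list[LandmarkFrame],
                        visibility_threshold: float = 0.5) -> np.ndarray:
    """Per-frame posture flags: PRONE (1), UPRIGHT (0) or OCCLUDED (-1)."""
    flags = np.empty(len(frames), dtype=np.int8)
    for i, fr in enumerate(frames):
        box = bounding_box(fr, visibility_threshold)
        ar = aspect_ratio(box) if box is not None else None
        if ar is None:
            flags[i] = OCCLUDED
        else:
            flags[i] = PRONE if ar[1] else UPRIGHT
    return flags


def prone_streak(flags: np.ndarray, required: int = FRAMES_PER_SEGMENT,
                 occlusion_gap: int = 0) -> tuple[bool, int]:
    """Temporal vote: (confirmed, longest_run).

    Confirmation requires ``required`` strictly adjacent prone frames.  Any
    upright frame resets the run; occluded frames also reset it unless up to
    ``occlusion_gap`` consecutive occluded frames are tolerated (default 0,
    i.e. strict adjacency).
    """
    if required < 1:
        raise ValueError("required must be >= 1")
    flags = np.asarray(flags)
    best = run = 0
    occl = 0
    for f in flags:
        if f == PRONE:
            run += 1
            occl = 0
        elif f == OCCLUDED and occl < occlusion_gap:
            occl += 1  # tolerated gap: run neither grows nor resets
        else:
            run = 0
            occl = 0
        best = max(best, run)
    return best >= required, best


def streak_membership(flags: np.ndarray, required: int = FRAMES_PER_SEGMENT
                      ) -> np.ndarray:
    """Boolean per-frame mask: frame belongs to a prone run of length >=
    ``required`` (strict adjacency, occlusions reset)."""
    flags = np.asarray(flags)
    member = np.zeros(len(flags), dtype=bool)
    i = 0
    while i < len(flags):
        if flags[i] == PRONE:
            j = i
            while j < len(flags) and flags[j] == PRONE:
                j += 1
            if j - i >= required:
                member[i:j] = True
            i = j
        else:
            i += 1
    return member


def make_segments(frames: list[LandmarkFrame],
                  labels_fn=None) -> list[PoseSegment]:
    """Tile a frame stream into non-overlapping 30-frame segments.

    ``labels_fn(interval) -> 0/1`` optionally labels each segment from its
    time span; incomplete trailing frames are dropped.
    """
    segs = []
    n_full = len(frames) // FRAMES_PER_SEGMENT
    for k in range(n_full):
        chunk = frames[k * FRAMES_PER_SEGMENT:(k + 1) * FRAMES_PER_SEGMENT]
        feats = np.stack([fr.landmarks[:, :2].ravel() for fr in chunk])
        interval = (chunk[0].timestamp, chunk[-1].timestamp)
        label = labels_fn(interval) if labels_fn is not None else None
        segs.append(PoseSegment(features=feats, interval=interval, label=label))
    return segs


class PoseTransformer(BaseEstimator, ClassifierMixin):
    """Transformer classifier over 30 x 66 pose segments (sklearn-style).

    The study architecture is 4 encoder layers, 8 attention heads and a
    256-dim model over 30-frame / 66-feature inputs, trained with Adam,
    cross-entropy, cosine annealing and early stopping (lr 1e-4, batch 64,
    40 epochs, patience 5); an alternative plain-Adam recipe (lr 3e-4, no
    annealing) is selectable by construction.

    Attributes
    ----------
    net_ : trained :class:`~nightfall.nn.TransformerClassifierNet`.
    classes_ : ``array([0, 1])`` (normal, fallen).
    history_ : per-epoch train/validation loss records.
    """

    def __init__(self, d_model=256, n_layers=4, n_heads=8,
                 lr=1e-4, batch_size=64, epochs=40, patience=5,
                 cosine_annealing=True, val_frac=0.15, test_frac=0.15,
                 random_state=0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.cosine_annealing = cosine_annealing
        self.val_frac = val_frac
        self.test_frac = test_frac
        self.random_state = random_state

    def fit(self, X, y):
        X = self._validate(X)
        y = np.asarray(y, dtype=np.int64)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.net_ = TransformerClassifierNet(
            d_in=FEATURE_DIM, d_model=self.d_model, n_layers=self.n_layers,
            n_heads=self.n_heads, seq_len=FRAMES_PER_SEGMENT, n_classes=2,
            seed=self.random_state)
        recipe = TrainRecipe(lr=self.lr, batch_size=self.batch_size,
                             epochs=self.epochs, patience=self.patience,
                             val_frac=self.val_frac, test_frac=self.test_frac,
                             cosine_annealing=self.cosine_annealing)
        info = fit_classifier(self.net_, X, y, recipe, seed=self.random_state)
        self.history_ = info["history"]
        self.split_sizes_ = info["split_sizes"]
        self.test_accuracy_ = info.get("test_accuracy")
        self.n_parameters_ = self.net_.n_parameters()
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        out = np.empty((len(X), 2))
        for lo in range(0, len(X), 256):
            out[lo:lo + 256] = self.net_.predict_proba(X[lo:lo + 256])
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != (FRAMES_PER_SEGMENT, FEATURE_DIM):
            raise ValueError(
                f"X must be (n, {FRAMES_PER_SEGMENT}, {FEATURE_DIM}), got {X.shape}")
        return X


def vision_probability(p_transformer: float, segment_confirmed: bool,
                       mode: str = "gated", attenuation: float = 0.5
                       ) -> float:
    """Combine the Transformer probability with the posture confirmation.

    mode "gated" (default): p unchanged when a >=30-frame prone run
    intersects the segment, multiplied by ``attenuation`` otherwise;
    mode "raw": the Transformer probability as-is; mode "hard_and": p when
    confirmed, 0 otherwise.
    """
    if not 0.0 <= p_transformer <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    if mode == "raw":
        return p_transformer
    if mode == "gated":
        return p_transformer if segment_confirmed else attenuation * p_transformer
    if mode == "hard_and":
        return p_transformer if segment_confirmed else 0.0
    raise ValueError(f"unknown mode {mode!r}")
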