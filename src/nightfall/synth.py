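"""Synthetic bimodal cohort simulator.

Generates synchronized 6-axis IMU streams (50 Hz, accelerations in g,
angular velocities in deg/s) and 33-landmark 2-D pose streams (30 fps,
coordinates normalized to [0, 1] with visibility scores), for scripted
two-minute trials of simulated falls (forward / backward / lateral) and
routine nocturnal activities (lying down, rolling over, sitting up,
standing up, walking).

The templates are piecewise kinematic primitives chosen so that the cues the
detection pipeline relies on are present by construction:

* falls: quiescent upright phase -> rapid trunk rotation with a brief
  free-fall dip -> an impact impulse (peak drawn uniformly from a
  configurable range, default 2-6 g) -> near-zero motion lying on the floor
  (landmark cloud wider than tall);
* activities of daily living (ADLs): smooth low-frequency trajectories whose
  acceleration magnitude stays below a configurable cap, without the
  impulse-then-stillness signature.

Sensor imperfections are emulated by additive Gaussian noise on the IMU
channels, landmark jitter, per-frame visibility dropouts (i.i.d. or in
occlusion bursts) and loose clock synchronization (a constant per-stream
start offset plus bounded per-sample timestamp noise).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FALL_KINDS",
    "ADL_KINDS",
    "ActivityScript",
    "NoiseConfig",
    "TemplateConfig",
    "TrialRecording",
    "CohortManifest",
    "generate_trial",
    "generate_cohort",
]

IMU_RATE_HZ = 50.0
POSE_FPS = 30.0
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

FALL_KINDS = ("fall_forward", "fall_backward", "fall_lateral")
ADL_KINDS = ("lie_down", "roll_over", "sit_up", "stand_up", "walk")

# canonical body-frame landmark layout: (s, u) = (longitudinal, lateral)
# offsets in body-length / body-width units; s = +0.5 is the head end.
_LANDMARK_S = np.array([
    0.50, 0.52, 0.52, 0.52, 0.52, 0.52, 0.52, 0.48, 0.48, 0.44, 0.44,   # face
    0.35, 0.35, 0.20, 0.20, 0.05, 0.05, 0.02, 0.02, 0.03, 0.03, 0.05, 0.05,  # arms
    0.00, 0.00, -0.25, -0.25, -0.48, -0.48, -0.50, -0.50, -0.52, -0.52,  # legs
])
_LANDMARK_U = np.array([
    0.00, -0.10, -0.12, -0.14, 0.10, 0.12, 0.14, -0.20, 0.20, -0.08, 0.08,
    -0.55, 0.55, -0.70, 0.70, -0.75, 0.75, -0.80, 0.80, -0.78, 0.78, -0.72, 0.72,
    -0.30, 0.30, -0.32, 0.32, -0.30, 0.30, -0.28, 0.28, -0.35, 0.35,
])
N_LANDMARKS = 33


@dataclass(frozen=True)
class ActivityScript:
    """One scripted trial: what the subject does and when."""

    activity_kind: str
    duration: float = 120.0
    event_interval: tuple[float, float] | None = None
    subject_params: dict = field(default_factory=dict)

    @property
    def is_fall(self) -> bool:
        return self.activity_kind in FALL_KINDS

    def __post_init__(self):
        if self.activity_kind not in FALL_KINDS + ADL_KINDS:
            raise ValueError(f"unknown activity kind {self.activity_kind!r}")
        if self.duration < 2.0:
            raise ValueError("duration must be at least 2 s")
        if self.is_fall:
            if self.event_interval is None:
                raise ValueError("fall scripts require an event_interval")
            lo, hi = self.event_interval
            if not (0.0 <= lo < hi <= self.duration):
                raise ValueError(
                    f"event_interval {self.event_interval} does not fit in "
                    f"duration {self.duration} s")
        elif self.event_interval is not None:
            raise ValueError("event_interval is only valid for fall scripts")


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-imperfection parameters."""

    accel_noise_g: float = 0.03
    gyro_noise_dps: float = 1.5
    landmark_jitter: float = 0.004
    dropout_prob: float = 0.02
    burst_prob: float = 0.0       # per-frame chance of starting an occlusion burst
    burst_len: int = 10           # frames per burst
    clock_offset_max_s: float = 0.1
    sample_jitter_sd_s: float = 0.001

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(accel_noise_g=0.0, gyro_noise_dps=0.0, landmark_jitter=0.0,
                   dropout_prob=0.0, burst_prob=0.0, clock_offset_max_s=0.0,
                   sample_jitter_sd_s=0.0)


@dataclass(frozen=True)
class TemplateConfig:
    """Kinematic template parameters (amplitudes, durations, caps)."""

    fall_impulse_range_g: tuple[float, float] = (2.0, 6.0)
    fall_impulse_peak_g: float | None = None  # fixed peak overrides the range
    descent_duration_s: float = 0.7
    adl_accel_cap_g: float = 1.8
    body_length: float = 0.45   # normalized image units at stature scale 1
    body_width: float = 0.11


@dataclass
class TrialRecording:
    """One trial's synchronized streams plus per-second ground truth."""

    subject_id: str
    script: ActivityScript
    imu_t: np.ndarray       # (N,) timestamps, s
    imu: np.ndarray         # (N, 6): ax, ay, az [g], gx, gy, gz [deg/s]
    pose_t: np.ndarray      # (M,) timestamps, s
    pose: np.ndarray        # (M, 33, 3): x_norm, y_norm, visibility
    ground_truth: np.ndarray  # (ceil(duration),) binary per-second fall label

    def validate(self) -> None:
        if self.imu.shape != (len(self.imu_t), 6):
            raise ValueError("IMU shape mismatch")
        if self.pose.shape != (len(self.pose_t), N_LANDMARKS, 3):
            raise ValueError("pose shape mismatch")
        if np.abs(self.imu[:, :3]).max(initial=0.0) > ACCEL_RANGE_G:
            raise ValueError("acceleration outside sensor range")
        if np.abs(self.imu[:, 3:]).max(initial=0.0) > GYRO_RANGE_DPS:
            raise ValueError("angular velocity outside sensor range")
        if self.pose.size and (self.pose.min() < 0.0 or self.pose.max() > 1.0):
            raise ValueError("pose values outside [0, 1]")


@dataclass
class CohortManifest:
    """A generated cohort: subject ids, their trials, and the seed used."""

    subjects: list[str]
    trials: dict[str, list[TrialRecording]]
    seed: int

    def all_trials(self) -> list[TrialRecording]:
        return [t for s in self.subjects for t in self.trials[s]]


# -- kinematic profiles --------------------------------------------------------

def _smoothstep(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """0 before lo, 1 after hi, smooth in between."""
    x = np.clip((t - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _orientation_profile(kind: str, t: np.ndarray, script: ActivityScript,
                         tpl: TemplateConfig, descent: float) -> np.ndarray:
    """Trunk angle in radians: pi/2 upright, 0 horizontal."""
    up = np.pi / 2
    if kind in FALL_KINDS:
        e0, _ = script.event_interval
        return up * (1.0 - _smoothstep(t, e0, e0 + descent))
    if kind == "lie_down":
        t0 = 0.30 * script.duration
        return up * (1.0 - _smoothstep(t, t0, t0 + 4.0))
    if kind == "roll_over":
        return np.zeros_like(t)
    if kind == "sit_up":
        t0 = 0.30 * script.duration
        return up * (0.05 + 0.61 * _smoothstep(t, t0, t0 + 2.5))
    if kind == "stand_up":
        t0 = 0.30 * script.duration
        return up * (0.60 + 0.40 * _smoothstep(t, t0, t0 + 2.0))
    return np.full_like(t, up)  # walk


def _imu_signals(script: ActivityScript, tpl: TemplateConfig, noise: NoiseConfig,
                 rng: np.random.Generator, peak_g: float) -> np.ndarray:
    """Template + noise on the nominal 50 Hz grid; returns (N, 6)."""
    kind = script.activity_kind
    n = int(round(script.duration * IMU_RATE_HZ))
    t = np.arange(n) / IMU_RATE_HZ
    descent = tpl.descent_duration_s / max(script.subject_params.get("descent_speed", 1.0), 0.2)
    phi = _orientation_profile(kind, t, script, tpl, descent)

    # gravity in the sensor frame; lateral falls rotate into the y axis
    lateral = kind == "fall_lateral"
    sign = -1.0 if kind == "fall_backward" else 1.0
    ax = sign * np.cos(phi)
    ay = np.zeros_like(t)
    az = np.sin(phi)
    if lateral:
        ax, ay = ay, ax
    gx = np.zeros_like(t)
    gy = np.zeros_like(t)
    gz = np.zeros_like(t)
    # trunk angular rate from the orientation profile
    rate = np.gradient(phi, 1.0 / IMU_RATE_HZ) * 180.0 / np.pi  # deg/s
    if lateral:
        gx += rate
    else:
        gy += rate

    if kind in FALL_KINDS:
        e0, _ = script.event_interval
        impact = e0 + descent
        # free-fall dip during the descent
        dip = _smoothstep(t, e0, e0 + 0.6 * descent) - _smoothstep(
            t, e0 + 0.6 * descent, impact + 0.05)
        scale = 1.0 - 0.7 * np.clip(dip, 0.0, 1.0)
        ax, ay, az = ax * scale, ay * scale, az * scale
        # impact impulse: half-sine of 120 ms centred on a sample tick so the
        # configured peak is attained exactly in the noise-free case
        ic = round(impact * IMU_RATE_HZ) / IMU_RATE_HZ
        width = 0.12
        in_pulse = np.abs(t - ic) <= width / 2
        shape = np.cos(np.pi * (t - ic) / width) ** 2 * in_pulse
        u = {"fall_forward": (1.0, 0.0, 0.3), "fall_backward": (-1.0, 0.0, 0.3),
             "fall_lateral": (0.0, 1.0, 0.3)}[kind]
        u = np.array(u) / np.linalg.norm(u)
        base = np.stack([ax, ay, az], axis=1)
        mix = shape[:, None]
        pulse = u[None, :] * (peak_g * shape)[:, None]
        acc = base * (1.0 - mix) + pulse
        ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
        gz += 50.0 * shape * rng.standard_normal()
    elif kind == "walk":
        step = 1.9  # Hz
        bob = 0.35 * np.sin(2 * np.pi * step * t) + 0.12 * np.sin(2 * np.pi * 2 * step * t + 0.7)
        az = az + bob
        ax = ax + 0.10 * np.sin(2 * np.pi * step * t + 1.2)
        gy += 25.0 * np.sin(2 * np.pi * step * t + 0.3)
        gz += 15.0 * np.sin(2 * np.pi * step / 2 * t)
    elif kind == "roll_over":
        t0 = 0.30 * script.duration
        roll = _smoothstep(t, t0, t0 + 1.5) - _smoothstep(t, t0 + 1.5, t0 + 3.0)
        gx += 85.0 * roll
        ay = ay + 0.35 * roll * np.sin(2 * np.pi * 0.8 * (t - t0))
    elif kind in ("sit_up", "stand_up"):
        t0 = 0.30 * script.duration
        bump = np.exp(-0.5 * ((t - (t0 + 1.0)) / 0.35) ** 2)
        amp = 0.55 if kind == "sit_up" else 0.65
        az = az + amp * bump
        ax = ax + 0.2 * bump
    # lie_down: the smooth orientation profile is the whole story

    acc = np.stack([ax, ay, az], axis=1)
    if kind not in FALL_KINDS:
        mag = np.linalg.norm(acc, axis=1, keepdims=True)
        over = mag > tpl.adl_accel_cap_g
        acc = np.where(over, acc * tpl.adl_accel_cap_g / np.maximum(mag, 1e-9), acc)
    gyro = np.stack([gx, gy, gz], axis=1)
    acc = acc + noise.accel_noise_g * rng.standard_normal(acc.shape)
    gyro = gyro + noise.gyro_noise_dps * rng.standard_normal(gyro.shape)
    acc = np.clip(acc, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return np.concatenate([acc, gyro], axis=1)


def _pose_frames(script: ActivityScript, tpl: TemplateConfig, noise: NoiseConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Landmark stream on the nominal 30 fps grid; returns (M, 33, 3)."""
    kind = script.activity_kind
    m = int(round(script.duration * POSE_FPS))
    t = np.arange(m) / POSE_FPS
    descent = tpl.descent_duration_s / max(script.subject_params.get("descent_speed", 1.0), 0.2)
    phi = _orientation_profile(kind, t, script, tpl, descent)
    stature = script.subject_params.get("stature_scale", 1.0)
    L = tpl.body_length * stature
    W = tpl.body_width * stature

    cx = np.full(m, 0.5)
    cy = np.full(m, 0.55)
    if kind == "walk":
        cx = 0.5 + 0.2 * np.sin(2 * np.pi * 0.12 * t)
        cy = cy + 0.01 * np.sin(2 * np.pi * 1.9 * t)
    # the body centre sinks as the trunk goes horizontal (floor/bed level)
    cy = cy + 0.18 * (1.0 - np.sin(phi))

    axis = np.stack([np.cos(phi), -np.sin(phi)], axis=1)      # (M, 2)
    perp = np.stack([np.sin(phi), np.cos(phi)], axis=1)
    s = _LANDMARK_S[None, :, None] * L          # (1, 33, 1)
    u = _LANDMARK_U[None, :, None] * W
    xy = (np.stack([cx, cy], axis=1)[:, None, :]
          + s * axis[:, None, :] + u * perp[:, None, :])       # (M, 33, 2)
    if kind == "roll_over":
        t0 = 0.30 * script.duration
        squeeze = 1.0 - 0.35 * (_smoothstep(t, t0, t0 + 1.5)
                                - _smoothstep(t, t0 + 1.5, t0 + 3.0))
        xy[:, :, 1] = cy[:, None] + (xy[:, :, 1] - cy[:, None]) * squeeze[:, None]
    xy = xy + noise.landmark_jitter * rng.standard_normal(xy.shape)
    xy = np.clip(xy, 0.0, 1.0)

    vis = rng.uniform(0.7, 1.0, size=(m, N_LANDMARKS))
    if noise.dropout_prob > 0:
        drop = rng.random((m, N_LANDMARKS)) < noise.dropout_prob
        vis = np.where(drop, rng.uniform(0.0, 0.45, size=vis.shape), vis)
    if noise.burst_prob > 0:
        starts = np.flatnonzero(rng.random(m) < noise.burst_prob)
        for s0 in starts:
            vis[s0:s0 + noise.burst_len] = np.minimum(
                vis[s0:s0 + noise.burst_len], 0.3)
    return np.concatenate([xy, vis[:, :, None]], axis=2)


def _jittered_times(n: int, rate: float, noise: NoiseConfig,
                    rng: np.random.Generator) -> np.ndarray:
    offset = rng.uniform(-noise.clock_offset_max_s, noise.clock_offset_max_s) \
        if noise.clock_offset_max_s > 0 else 0.0
    jitter = rng.normal(0.0, noise.sample_jitter_sd_s, size=n) \
        if noise.sample_jitter_sd_s > 0 else np.zeros(n)
    half_step = 0.5 / rate
    jitter = np.clip(jitter, -0.8 * half_step, 0.8 * half_step)  # keep monotone
    return offset + np.arange(n) / rate + jitter


def generate_trial(script: ActivityScript, noise: NoiseConfig | None = None,
                   seed: int = 0, template: TemplateConfig | None = None,
                   subject_id: str = "S00") -> TrialRecording:
    """Simulate one trial's IMU and pose streams.

    Identical (script, noise, template, seed) always yield identical output.
    """
    noise = noise or NoiseConfig()
    template = template or TemplateConfig()
    rng = np.random.default_rng(seed)
    if script.is_fall:
        e0, _ = script.event_interval
        descent = template.descent_duration_s / max(
            script.subject_params.get("descent_speed", 1.0), 0.2)
        if e0 + descent + 0.2 > script.duration:
            raise ValueError(
                f"duration {script.duration} s too short for a fall event "
                f"starting at {e0} s (descent {descent:.2f} s)")
        if template.fall_impulse_peak_g is not None:
            peak = template.fall_impulse_peak_g
        else:
            lo, hi = template.fall_impulse_range_g
            peak = rng.uniform(lo, hi)
        peak *= script.subject_params.get("impulse_scale", 1.0)
    else:
        peak = 0.0
    imu = _imu_signals(script, template, noise, rng, peak)
    pose = _pose_frames(script, template, noise, rng)
    imu_t = _jittered_times(len(imu), IMU_RATE_HZ, noise, rng)
    pose_t = _jittered_times(len(pose), POSE_FPS, noise, rng)
    n_sec = int(np.ceil(script.duration))
    gt = np.zeros(n_sec, dtype=np.int8)
    if script.is_fall:
        e0, e1 = script.event_interval
        for k in range(n_sec):
            if k < e1 and k + 1 > e0:
                gt[k] = 1
    rec = TrialRecording(subject_id=subject_id, script=script, imu_t=imu_t,
                         imu=imu, pose_t=pose_t, pose=pose, ground_truth=gt)
    rec.validate()
    return rec


def _draw_subject_params(rng: np.random.Generator) -> dict:
    return {
        "stature_scale": float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15)),
        "descent_speed": float(np.clip(rng.normal(1.0, 0.10), 0.7, 1.3)),
        "impulse_scale": float(np.clip(rng.normal(1.0, 0.15), 0.6, 1.5)),
    }


def generate_cohort(n_subjects: int = 16, trials_per_subject: int = 30,
                    seed: int = 0, duration: float = 120.0,
                    noise: NoiseConfig | None = None,
                    template: TemplateConfig | None = None,
                    fall_fraction: float = 0.5) -> CohortManifest:
    """Simulate a cohort: per-subject kinematic modifiers drawn once, then
    ``trials_per_subject`` trials split ``fall_fraction`` / 1-``fall_fraction``
    between falls and ADLs (default 50/50)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    n_falls = fall_fraction * trials_per_subject
    if abs(n_falls - round(n_falls)) > 1e-9:
        raise ValueError(
            f"trials_per_subject={trials_per_subject} cannot be split with "
            f"fall fraction {fall_fraction}")
    n_falls = int(round(n_falls))
    noise = noise or NoiseConfig()
    template = template or TemplateConfig()
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    subjects = [f"S{i:02d}" for i in range(n_subjects)]
    trials: dict[str, list[TrialRecording]] = {}
    for sid, sseq in zip(subjects, subj_seeds):
        srng = np.random.default_rng(sseq)
        params = _draw_subject_params(srng)
        kinds = [FALL_KINDS[i % len(FALL_KINDS)] for i in range(n_falls)]
        kinds += [ADL_KINDS[i % len(ADL_KINDS)]
                  for i in range(trials_per_subject - n_falls)]
        recs = []
        for ti, kind in enumerate(kinds):
            if kind in FALL_KINDS:
                e0 = float(srng.uniform(0.3 * duration, 0.7 * duration))
                # the event spans the dynamic phase: descent + impact settling
                descent = template.descent_duration_s / max(
                    params.get("descent_speed", 1.0), 0.2)
                ev = (e0, min(e0 + descent + 0.8, duration))
            else:
                ev = None
            script = ActivityScript(activity_kind=kind, duration=duration,
                                    event_interval=ev, subject_params=params)
            trial_seed = int(srng.integers(0, 2 ** 31 - 1))
            recs.append(generate_trial(script, noise, trial_seed, template,
                                       subject_id=sid))
        trials[sid] = recs
    return CohortManifest(subjects=subjects, trials=trials, seed=seed)
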