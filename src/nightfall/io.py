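"""Readers/writers and run configuration.

Formats (all plain text):

* IMU stream: CSV with header ``t,ax,ay,az,gx,gy,gz`` — seconds, g, deg/s;
* pose stream: line-delimited JSON records
  ``{"t": <s>, "landmarks": [[x, y, visibility] x 33]}``;
* cohort manifest, run manifests, metric reports: JSON;
* run configuration: YAML or JSON, lossless round-trip.

Timestamps are seconds as decimal numbers and need not start at zero; the
pipeline aligns streams by timestamp, never by index, because the simulated
clocks are only loosely synchronized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import (ACCEL_RANGE_G, GYRO_RANGE_DPS, N_LANDMARKS, ActivityScript,
                    CohortManifest, NoiseConfig, TrialRecording)

__all__ = [
    "RunConfig",
    "read_imu_csv", "write_imu_csv",
    "read_pose_jsonl", "write_pose_jsonl",
    "write_trial", "read_trial",
    "write_cohort", "read_cohort",
    "write_run_manifest",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with the study defaults."""

    imu_rate_hz: float = 50.0
    pose_fps: float = 30.0
    window_samples: int = 60
    window_overlap: float = 0.5
    frames_per_segment: int = 30
    band_low_hz: float = 0.2
    band_high_hz: float = 20.0
    filter_order: int = 4
    visibility_threshold: float = 0.5
    tau_percentile: float = 95.0
    alpha: float = 0.70
    prone_streak_frames: int = 30
    vision_mode: str = "gated"
    attenuation: float = 0.5
    ae_hidden: list = field(default_factory=lambda: [128, 128])
    ae_lr: float = 1e-3
    ae_batch: int = 32
    ae_epochs: int = 50
    ae_patience: int = 10
    tr_d_model: int = 256
    tr_layers: int = 4
    tr_heads: int = 8
    tr_lr: float = 1e-4
    tr_batch: int = 64
    tr_epochs: int = 40
    tr_patience: int = 5
    tr_cosine: bool = True
    fewshot_lr: float = 1e-4
    fewshot_iters: int = 50
    seed: int = 0

    def to_file(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# -- IMU CSV -------------------------------------------------------------------

def write_imu_csv(path, t: np.ndarray, imu: np.ndarray) -> None:
    df = pd.DataFrame(np.column_stack([t, imu]), columns=IMU_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_imu_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read and validate an IMU CSV; returns (t, (N, 6) values)."""
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # bad[0] indexes the step; the offending sample is the next row,
        # +2 more for the header line and 1-based file numbering
        raise ValueError(f"{path}: non-monotone timestamp at row {bad[0] + 3}")
    vals = df[IMU_COLUMNS[1:]].to_numpy(float)
    over_a = np.abs(vals[:, :3]) > ACCEL_RANGE_G
    if over_a.any():
        row = int(np.argwhere(over_a)[0, 0])
        raise ValueError(f"{path}: acceleration outside ±{ACCEL_RANGE_G:g} g "
                         f"sensor range at row {row + 2}")
    over_g = np.abs(vals[:, 3:]) > GYRO_RANGE_DPS
    if over_g.any():
        row = int(np.argwhere(over_g)[0, 0])
        raise ValueError(f"{path}: angular velocity outside "
                         f"±{GYRO_RANGE_DPS:g} deg/s sensor range at row {row + 2}")
    gaps = np.flatnonzero(np.diff(t) > 0.1)
    if gaps.size:
        print(f"{path}: {gaps.size} timestamp gaps > 100 ms", file=sys.stderr)
    return t, vals


# -- pose JSONL ----------------------------------------------------------------

def write_pose_jsonl(path, t: np.ndarray, pose: np.ndarray) -> None:
    with open(path, "w") as fh:
        for ti, frame in zip(t, pose):
            rec = {"t": round(float(ti), 6),
                   "landmarks": [[round(float(v), 6) for v in lm] for lm in frame]}
            fh.write(json.dumps(rec) + "\n")


def read_pose_jsonl(path) -> tuple[np.ndarray, np.ndarray]:
    """Read and validate a pose JSONL; returns (t, (M, 33, 3) landmarks)."""
    ts, frames = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            lm = np.asarray(rec["landmarks"], dtype=float)
            if lm.shape != (N_LANDMARKS, 3):
                raise ValueError(f"{path}: line {ln}: expected {N_LANDMARKS} "
                                 f"landmarks, got shape {lm.shape}")
            if lm.min() < 0.0 or lm.max() > 1.0:
                raise ValueError(f"{path}: line {ln}: landmark value outside [0, 1]")
            ts.append(float(rec["t"]))
            frames.append(lm)
    return np.asarray(ts), np.asarray(frames)


# -- trials and cohorts --------------------------------------------------------

def write_trial(directory, trial: TrialRecording, stem: str) -> dict:
    """Write one trial's streams; returns its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    imu_path = directory / f"{stem}_imu.csv"
    pose_path = directory / f"{stem}_pose.jsonl"
    write_imu_csv(imu_path, trial.imu_t, trial.imu)
    write_pose_jsonl(pose_path, trial.pose_t, trial.pose)
    return {
        "subject_id": trial.subject_id,
        "activity_kind": trial.script.activity_kind,
        "duration": trial.script.duration,
        "event_interval": list(trial.script.event_interval)
        if trial.script.event_interval else None,
        "subject_params": trial.script.subject_params,
        "imu": imu_path.name,
        "pose": pose_path.name,
        "ground_truth": [int(v) for v in trial.ground_truth],
    }


def read_trial(directory, entry: dict) -> TrialRecording:
    directory = Path(directory)
    t_imu, imu = read_imu_csv(directory / entry["imu"])
    t_pose, pose = read_pose_jsonl(directory / entry["pose"])
    script = ActivityScript(
        activity_kind=entry["activity_kind"], duration=entry["duration"],
        event_interval=tuple(entry["event_interval"]) if entry["event_interval"] else None,
        subject_params=entry.get("subject_params", {}))
    return TrialRecording(subject_id=entry["subject_id"], script=script,
                          imu_t=t_imu, imu=imu, pose_t=t_pose, pose=pose,
                          ground_truth=np.asarray(entry["ground_truth"], dtype=np.int8))


def write_cohort(directory, cohort: CohortManifest) -> Path:
    """Write every trial plus a single JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid in cohort.subjects:
        for ti, trial in enumerate(cohort.trials[sid]):
            entries.append(write_trial(directory, trial, f"{sid}_T{ti:02d}"))
    manifest = {"seed": cohort.seed, "subjects": cohort.subjects,
                "trials": entries}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(manifest_path) -> CohortManifest:
    manifest_path = Path(manifest_path)
    data = json.loads(manifest_path.read_text())
    trials: dict[str, list[TrialRecording]] = {s: [] for s in data["subjects"]}
    for entry in data["trials"]:
        trials[entry["subject_id"]].append(
            read_trial(manifest_path.parent, entry))
    return CohortManifest(subjects=data["subjects"], trials=trials,
                          seed=data["seed"])


def write_run_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """Provenance record written alongside every CLI run's outputs."""
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(config),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
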