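# nightfall

Bimodal fall detection for nocturnal home monitoring: an inertial branch and
a vision branch, fused at the decision level.

Falls among older adults living alone are a leading cause of injury, and the
hard part of detecting them automatically is not sensitivity but false
alarms: waist-worn inertial sensors confuse abrupt-but-benign movements
(sitting down hard, rolling over) with impacts, while camera-based systems
degrade in a dark bedroom under occlusion by blankets and furniture.
`nightfall` implements a detector that requires *agreement* between two
independent sensing streams before raising an alarm, together with the full
evaluation protocol needed to quantify that design choice — leave-one-
subject-out (LOSO) cross-validation, few-shot personalization, and a
subject-wise learning curve — all exercisable end-to-end on a bundled
synthetic multimodal simulator, so no data download is required.

## The method

**Inertial branch (unsupervised anomaly detection).** A 6-axis IMU stream
(tri-axial acceleration in g, angular velocity in deg/s, 50 Hz) is band-pass
filtered (4th-order Butterworth, 0.2–20 Hz, applied forward–backward so the
result is zero-phase), z-scored per channel with training-set statistics,
and segmented into windows of T = 60 samples (1.2 s) with 50% overlap.
An LSTM autoencoder (two stacked 128-unit encoder layers, a 256-dim latent
vector, a symmetric decoder and a 256→6 dense read-out) is trained on
non-fall motion only; a window's anomaly is its reconstruction error

    MSE(n) = (1/T) Σₜ ‖xₙ(t) − x̂ₙ(t)‖²,

thresholded at τ, the 95th percentile of the training errors, and bounded
into a fusion score

    s_anomaly = min(MSE(n)/τ, 1).

**Vision branch (pose-sequence classification).** Per video frame (30 fps),
33 two-dimensional skeletal landmarks with visibility scores — produced
upstream by any pose estimator; this package consumes them as line-delimited
records. Landmarks with visibility > 0.5 define a bounding box whose aspect
ratio ρ = width/height is a coarse posture cue (ρ > 1: horizontal body); a
fall is posture-confirmed only after 30 strictly adjacent prone frames
(1 s of temporal voting — occluded frames reset the run). In parallel, a
Transformer encoder (4 layers, 8 heads, model dim 256) classifies
non-overlapping 30-frame segments of the 66-dim flattened coordinates into
fallen/normal, and the per-second vision probability p_fall is the
Transformer output, attenuated when the posture cue withholds confirmation.

**Decision-level fusion.** Per 1-s epoch, with a common threshold α = 0.70:

    FALL            if p_fall > α  and  s_anomaly > α
    LOW_CONFIDENCE  if exactly one score exceeds α
    NORMAL          otherwise

A small trainable fusion head (a two-input threshold-gate network, 65
parameters, initialized to reproduce the AND rule) supports few-shot
personalization: with K ≤ 10 labeled 1-s sequences from a new subject, only
the head is fine-tuned (SGD, lr 1e-4, 50 iterations) while both branch
encoders stay frozen.

The neural networks are implemented on a compact numpy reverse-mode
autodiff core bundled with the package (`nightfall.nn`), so the whole
pipeline runs on a plain CPU with no deep-learning framework.

## Worked example

Train both branches on a small simulated cohort, then score a fall trial
from an unseen subject (the scripted fall spans 9.0–10.5 s):

```python
from nightfall.synth import ActivityScript, NoiseConfig, generate_trial, generate_cohort
from nightfall import evaluate as ev
from nightfall.fusion import fuse, FusionConfig

cohort = generate_cohort(n_subjects=3, trials_per_subject=6, seed=5, duration=20.0)
pipe = ev.train_fold(cohort.all_trials(), ev.PipelineConfig.small(), seed=5)

script = ActivityScript("fall_lateral", duration=20.0, event_interval=(9.0, 10.5))
trial = generate_trial(script, NoiseConfig(), seed=99, subject_id="S99")
p, s, y = pipe.score_trial(trial)
print(f"tau = {pipe.autoencoder.tau_:.3f}")
for k in range(7, 13):
    lab = fuse(float(p[k]), float(s[k]), FusionConfig()).label
    print(f"{k:5d}  {p[k]:.3f}   {s[k]:.3f}      {lab}")
```

prints

```
tau = 3.328
epoch  p_fall  s_anomaly  label
    7  0.005   0.687      NORMAL
    8  0.005   1.000      LOW_CONFIDENCE
    9  0.980   1.000      FALL
   10  0.486   1.000      LOW_CONFIDENCE
   11  0.487   0.471      NORMAL
   12  0.487   0.396      NORMAL
```

Epoch 9 — the second containing the descent and impact — is the only one
where both branches agree, and the only FALL. The IMU impulse alone (epochs
8 and 10, `s_anomaly = 1.0`) is flagged LOW_CONFIDENCE, not FALL: this is
the fusion rule suppressing the inertial false alarms that plague
single-modality detectors.

The same pipeline is scriptable from the shell (`nightfall simulate`,
`train-imu`, `train-vision`, `calibrate`, `detect`, `evaluate-loso`,
`fewshot`, `learning-curve`); every run writes a manifest with the config
hash, seed and library versions next to its outputs.

## Layout

| module                 | contents                                                    |
|------------------------|-------------------------------------------------------------|
| `nightfall.synth`      | synthetic cohort simulator (scripted falls + ADLs)          |
| `nightfall.imu`        | filtering, windowing, `LstmAutoencoder`, τ calibration      |
| `nightfall.vision`     | landmark geometry, prone streak, `PoseTransformer`          |
| `nightfall.fusion`     | fusion rule, epoch alignment, trainable `FusionHead`        |
| `nightfall.metrics`    | confusion metrics, ROC/AUC, fold CIs, paired t-tests        |
| `nightfall.evaluate`   | LOSO driver, few-shot curve, learning curve                 |
| `nightfall.io` / `cli` | CSV/JSONL/JSON formats, configuration, subcommand CLI       |
| `nightfall.nn`         | numpy autodiff LSTM autoencoder + Transformer encoder       |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
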