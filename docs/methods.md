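# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `nightfall`, in the order the data flow through the
pipeline.

## Signal model and preprocessing

The inertial stream is a 6-channel series at 50 Hz: tri-axial acceleration
within ±16 g and tri-axial angular velocity within ±2000 deg/s (values
outside these sensor ranges are rejected at ingestion). Preprocessing is
**filter first, then z-score**: a 4th-order Butterworth band-pass
(0.2–20 Hz) applied forward–backward (`scipy.signal.sosfiltfilt`), so the
output is zero-phase and the effective order doubles, followed by
per-channel standardization. Normalizing before filtering would re-introduce
a nonzero mean through the filter transient, which is why the order is
fixed this way; both stages are exposed separately for ablation. The
z-score statistics are always computed on the *training* partition and
reused on held-out data, so no test-time information leaks into the
representation. A zero-variance channel is an error, not a silent pass.

Windows are T = 60 samples (1.2 s) with 50% overlap, starts at 0, 30, 60, …
samples; incomplete trailing windows are dropped rather than padded, and a
series shorter than one window yields an empty list rather than an error.

## Inertial anomaly detection

The autoencoder is a stacked-LSTM sequence-to-sequence model: encoder
layers of 128 + 128 hidden units whose final hidden states are concatenated
into a 256-dim latent vector; the decoder mirrors the encoder, driven at
every timestep by the repeated latent, and a dense 256→6 layer reads out
the reconstruction. Training uses Adam (lr 1e-3, batch 32, up to 50
epochs), MSE loss, a 15% validation split and early stopping with patience
10; the best-validation checkpoint is restored.

The per-window reconstruction error is the mean over the 60 timesteps of
the **squared Euclidean norm of the 6-dim residual** (no division by the
channel count). The alternative convention — additionally averaging over
channels — rescales every error and hence τ by the same factor 6, so
detection decisions are identical; only the convention above is used so
that τ and the errors are directly comparable.

τ is the 95th percentile (linear interpolation between order statistics,
`numpy.percentile` default) of the training reconstruction errors.
Calibration from fewer than 20 errors is allowed but flagged as degraded.
The bounded fusion score is `min(MSE/τ, 1)`; the binary abnormality flag
uses the strict inequality `MSE > τ`.

## Vision branch

Landmark streams are 33 (x, y) points normalized to [0, 1] plus a
visibility score per point, at 30 fps. Coordinates are converted to pixels
by multiplication with the frame dimensions (1920 × 1080 by default) and
kept real-valued. The bounding box is the min/max over landmarks with
visibility **strictly greater than** 0.5; fewer than two qualifying
landmarks marks the frame occluded. The posture cue is the aspect ratio
ρ = width/height with *prone* defined strictly as ρ > 1 — a perfectly
square box (ρ = 1) counts as not prone, and a zero-height box has
undefined posture. ρ is invariant to translating all landmarks and to
uniform scaling of both axes.

Temporal voting requires 30 strictly adjacent prone frames; upright and
occluded frames reset the run. An optional `occlusion_gap` parameter
tolerates short occlusion bursts inside a run (default 0, i.e. strict
adjacency); the default is strict because adjacency is what suppresses
transient jitter. A 1-s segment counts as posture-confirmed when any of
its frames belongs to a qualifying run, so a run that extends past the
segment boundary still confirms it.

The classifier is a pre-norm Transformer encoder: learned 66→256 input
projection, sinusoidal positional encoding, 4 layers × 8 heads,
feed-forward width 4× the model dimension, mean pooling over the 30
timesteps and a 2-logit softmax head (a 1-logit sigmoid variant would be
equivalent at the decision level; the 2-logit head is what is
implemented). Because the normalized coordinates have a small dynamic
range, the input is recentred at 0.5 and scaled ×4 and the positional
encoding is scaled by 0.3 before the sum — without this the positional
term dominates the signal and optimization stalls. Two training recipes
are wired: the canonical one (Adam lr 1e-4, cosine annealing, batch 64, 40
epochs, early-stopping patience 5) and a plain-Adam alternative (lr 3e-4),
selectable via the estimator's parameters. Standalone training uses a
class-stratified 70/15/15 train/validation/test split (largest-remainder
allocation makes the totals exact) and reports held-out accuracy; inside
LOSO the test split is disabled since the held-out subject *is* the test
set.

The per-segment vision probability is the Transformer's fallen-class
probability, gated by posture: unchanged when the segment is
posture-confirmed, multiplied by an attenuation of 0.5 otherwise. The
gating mode is configurable (`raw` disables it, `hard_and` zeroes
unconfirmed segments); the multiplicative gate is the default because it
preserves score ordering for ROC analysis while still blocking
unconfirmed segments from crossing α = 0.70 (0.5 · p ≤ 0.5 < α).

## Fusion and personalization

Scores are paired per 1-s epoch by timestamp, never by index (the
simulated clocks are only loosely synchronized): each vision segment takes
the **maximum** anomaly score among IMU windows whose centers lie within
±0.6 s of the segment center — the maximum because a 1.2 s window overlaps
two epochs and an impact anywhere in the epoch should count. An epoch with
no IMU window in range carries an explicit missing marker and can never be
labeled FALL (the rule is conjunctive).

The fusion rule uses strict inequalities at the common threshold α = 0.70
on both scores. LOW_CONFIDENCE is an output label only — no escalation
logic is attached to it.

The trainable fusion head exists for personalization. It is a two-input
network of 16 threshold-gate units h_j = σ(κ(w_j·x − θ_j)) with fixed
steepness κ = 25; at initialization two gates sit exactly at α on each
input and the output bias is the midpoint between the worst both-pass and
best one-pass gate sums evaluated 0.05 away from α, so the untuned head
reproduces the AND rule everywhere outside that band (verified on a
101×101 grid). The gate thresholds θ_j are explicit parameters multiplied
by κ, which makes the decision boundary sensitive enough that plain SGD at
the personalization recipe (lr 1e-4, exactly 50 full-batch iterations,
early stop only at exactly zero loss) can move it by ~0.1–0.2 score units —
a conventional weight/bias parameterization cannot adapt at that recipe.
Fine-tuning minimizes **sum-reduction** binary cross-entropy, so each
additional calibration example adds gradient mass: adaptation strength
grows with the shot count K and saturates once the examples are
confidently classified, which is the qualitative behaviour the few-shot
protocol measures. The head has 65 parameters, far under the 5000-parameter
budget for on-device adaptation.

## Evaluation protocols

The unit of evaluation is the 1-s decision epoch. An epoch's ground truth
is positive when it overlaps the scripted fall event by **more than
0.25 s**; the minimum overlap exists because an epoch grazing the event
tail by a few frames contains no fall dynamics, and labeling it positive
would poison both training and scoring. (Window exclusion for autoencoder
training uses any overlap, which is the conservative direction there.) A
secondary event-level view — a fall trial counts as detected if at least
one FALL epoch overlaps its event — is reported per fold.

LOSO: per fold, the autoencoder is trained on the non-fall windows of all
other subjects, τ calibrated on those training errors, the Transformer
trained on their labeled segments (fall segments oversampled to ~1:1,
since they are a small minority of each trial and a prior-predicting
classifier is a local optimum), and every epoch of the held-out subject is
scored. LOW_CONFIDENCE maps to not-FALL for the binary confusion counts
(the switchable alternative is exposed in the decision objects);
micro-averaging pools counts across folds before computing rates. For ROC
analysis the fused scalar score is min(p_fall, s_anomaly) — the natural
score of a conjunctive rule — with missing anomaly scores treated as 0.

Fold statistics: two-sided 95% confidence intervals use Student's t with
n−1 degrees of freedom (t ≈ 2.131 at 15 df); paired comparisons use the
classic paired t-test, with a zero-variance difference vector reported as
an explicit degenerate result rather than a division by zero. Ratios with
empty denominators (e.g. specificity with no negatives) are reported as
NaN, never silently as 0.

Few-shot: for each subject and each K in 1…10, a calibration set of
exactly K sequences is drawn class-stratified without replacement
(ceil(K/2) falls when available, rebalanced when a class is scarce), only
the fusion head is fine-tuned on it, and F1 is measured on the disjoint
remainder; the curve reports the across-fold mean (averaged over 10
sampling draws) with t-based CIs. The bundled subject-shift generator
emulates per-subject vision miscalibration (fall p_fall centred 0.15–0.35
below the population value) — the regime personalization is for.

Learning curve: for each cohort size m, random m-subject subsets are drawn
(10 repeats) and LOSO is run within each subset; the mean F1 per m is
fitted with the saturating exponential F1(n) = a − b·e^(−cn) by nonlinear
least squares (initialization a₀ = max mean, b₀ = a₀ − min mean, c₀ = 0.3;
non-convergence raises with diagnostics, no silent fallback). The
asymptote CI is a seeded 1000-resample bootstrap over the per-m repeats,
and saturation is declared when the fitted gain from m = 12 to m = 16 is
below 0.5 percentage points. On noiseless synthetic points the fit
recovers (a, b, c) to machine precision.

## The simulator

The generator's job is to carry the statistical structure the method
assumes, not biomechanical fidelity. Falls are piecewise kinematic
primitives: a quiescent upright phase, a descent (trunk angle rotating
90°→0° over ~0.7 s, scaled per subject, with a free-fall dip in
acceleration magnitude), an impact impulse (half-sine, 120 ms, peak drawn
uniformly from 2–6 g and centred on a sample tick so the configured peak
is attained exactly in the noise-free case), then near-zero motion lying
on the floor. ADLs are smooth low-frequency trajectories — lying down is
the same postural transition stretched over ~4 s, rolling over stays
horizontal with a gyroscopic burst, sitting/standing add moderate
(≤1.8 g, capped) acceleration bumps, walking oscillates at ~1.9 Hz — with
no impulse-then-stillness signature. The scripted event interval covers
the *dynamic* phase (descent + 0.8 s of settling): the post-fall lying
posture is deliberately labeled normal, exactly like lying in bed, so the
classifiers must key on dynamics rather than static pose.

Landmarks come from a fixed 33-point body-frame layout rotated with the
trunk; visibility dropouts are i.i.d. per landmark per frame (default
probability 0.02, emulating <5 lux occlusion) with an optional burst mode
for contiguous occlusions; clock looseness is a constant per-stream offset
(default bound ±100 ms) plus bounded per-sample timestamp noise, and
alignment downstream therefore uses timestamps only. Per-subject kinematic
modifiers (stature, descent speed, impulse magnitude) are drawn once per
subject, giving the inter-individual variability that LOSO and
personalization exercise. Everything is deterministic given the seed, with
per-trial seeds spawned from the cohort seed.

What the simulator does **not** emulate: camera projection and perspective
(landmarks live in a fronto-parallel plane), pose-estimator failure modes
other than visibility dropout (no landmark swaps or outlier jumps),
multi-person scenes, soft-tissue/sensor-mount artifacts, and real elderly
kinematics (slower, lower-impact falls). Passing results on synthetic
cohorts therefore demonstrate that the pipeline's machinery — cue
extraction, thresholding, fusion, protocols — behaves as specified when
the assumed cue structure is present; they are not evidence about
real-world detection rates.

## Problem sizes of the bundled experiments

The study-scale defaults (16 subjects × 30 two-minute trials, 128-unit
LSTMs, 256-dim Transformer) are wired as the configuration defaults. The
bundled end-to-end comparison (`nightfall.evaluate.scaled_cohort` +
`PipelineConfig.small`) is the package's scaled-down experiment: 8
subjects × 10 trials of 30 s, a 16-unit single-layer autoencoder (10
epochs), a 32-dim single-layer/2-head Transformer (16 epochs, lr 1e-3),
and per-fold training-set caps of 768 windows / 1024 segments. These sizes
were chosen once so a full LOSO comparison runs in minutes on a single
CPU while leaving the phenomenon of interest intact — on this cohort the
fused detector's micro FPR is strictly below both unimodal baselines with
fused F1 at least as high, reproducing the ordering the architecture is
designed for.

## Known limitations

* The numpy autodiff core is compact and correct (finite-difference
  checked) but not fast; study-scale architectures train slowly and are
  exercised in tests only at reduced size.
* No dropout or weight decay is implemented; early stopping is the only
  regularizer. At the bundled problem sizes this is adequate.
* The Transformer sees raw coordinates; explicit velocity features would
  likely help at small scale but are deliberately not added, to keep the
  input contract (30 × 66 flattened coordinates) exact.
* The fused ROC score min(p, s) is one of several reasonable scalarizations
  of a conjunctive rule; alternatives (product, calibrated head output)
  would change AUC slightly but not the decision rule itself.
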