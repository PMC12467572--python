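# Methods

`fallsense` implements a pre-impact fall-detection pipeline for a single
waist-mounted IMU (tri-axial accelerometer, ±16 g, and gyroscope,
±2000 deg/s, sampled at 40 Hz).  The task is three-class: non-fall
activity (including high-vibration tool use and jumps), same-level-fall
(SLF) critical phases, and fall-from-height (FFH) critical phases.  The
*critical phase* runs from the moment of balance loss to ground impact;
only pre-impact data is ever used, because the point of detection is to
fire a wearable airbag whose inflation takes ≈130 ms.

## Windowing and labeling

Recordings are cut into fixed 40-sample (1 s) windows starting at the
active-segment origin plus multiples of the stride (default 40 samples,
i.e. non-overlapping, to avoid near-duplicate windows leaking between
folds; online replay uses stride 1).  Each window is denoised with a
5-sample moving median filter (reflection padding).  At 40 Hz a 5-sample
kernel spans 125 ms — long enough to remove single-sample spikes, short
enough to preserve the ≤20 Hz band of human motion.  A consequence worth
knowing: a fall signature that occupies only the last 1–2 samples of a
window is largely removed by the median filter, so windows that barely
graze a critical phase are genuinely ambiguous.

A window from a fall recording is labeled with the fall class iff its
**last** sample lies in the half-open critical phase
`[loss_of_balance, impact)`; windows ending earlier are non-fall, and
windows reaching the impact or beyond are discarded.  Keying the label to
the window end (rather than full containment) is what lets SLF critical
phases of 0.3–0.5 s — shorter than the window — produce fall-labeled
windows, and it makes the achievable lead time approximately the critical-
phase duration.

## Two-stage features (24 × 7 = 168)

Stage 1 expands a 40×6 window into 24 per-time-step channels:

* per sensor (accelerometer, gyroscope): the L2 magnitude (SMV), the L1
  magnitude (the per-sample SMA series, whose window mean is the classic
  signal-magnitude area), and six cross-axis statistics over the three
  axis values at each instant — min, mean, max, range, std, var
  (population convention, n = 3);
* accelerometer only: gravity-referenced roll `atan2(ay, az)` and pitch
  `atan2(−ax, √(ay²+az²))` in degrees, with `atan2(0,0) := 0` so free-fall
  windows stay finite;
* the six raw channels.

That is 10 accelerometer + 8 gyroscope + 6 raw channels.  Stage 2
condenses each channel into seven descriptive statistics over the window:
min, mean, max, variance, standard deviation, skewness and excess
kurtosis.  All moments are population moments (divide by n = 40);
skewness is Fisher–Pearson `m3/m2^1.5`; kurtosis is `m4/m2² − 3`; both
are defined as 0 when `m2 < 1e−12`.  The 10+8+6 channel split is the
unique natural decomposition that reproduces the printed dimensionality
of 168 = 24 × 7; whether the original feature set used exactly this
split, or bias-corrected estimators, is not documented anywhere we could
check, so the population convention is fixed here and frozen in the
feature-name registry (`<channel>__<stat>`).  Selection results are
always reported by name, never by column index.

Note the whole feature vector is invariant to permuting the time order of
samples within a window — the temporal structure enters only through the
stage-1 series' shape, not through any autocorrelation-type statistic.

## Class weighting

With N training rows, K classes and class sizes n_c, each row gets the
inverse-frequency weight `w_i = N / (K · n_c(i))`.  Every class then
carries the same total weight and `Σ w_i = N` exactly.  The weights enter
the boosters' loss directly (`sample_weight`).

## Feature selection

Two selectors run against a fitted booster and a validation split.

**SHAP-Select.**  Exact TreeSHAP contributions φ_ijk (observation i,
feature j, class k) are computed by the boosters' built-in tree-path
algorithm — no sampling, hence deterministic.  A multinomial logistic
regression is then fitted with the true label as response and linear
predictor `η_ik = Σ_j β_j φ_ijk`: one shared coefficient per feature
across the class logits (J coefficients total, the direct multiclass
generalization of the regression-on-SHAP scheme).  The fit maximizes the
softmax likelihood with a ridge penalty of 1e−6 (L-BFGS, analytic
gradient); Wald standard errors come from the penalized observed
information.  A feature is kept when β_j > 0 and p_j < α/J (Bonferroni
over the J = 168 coefficients, α = 0.05); the *non-negative* variant
keeps everything not significantly negative.

*Separation guard.*  On cleanly separable data the unpenalized MLE
diverges and the Wald SEs collapse to the pure-penalty bound
`1/√(2λ)`, making every p-value 1.  The fit therefore escalates the
ridge through 1e−6 → 1e−2 → 1.0 while the likelihood is saturated (mean
top-class probability > 0.999) or L-BFGS fails, and flags the escalation
in the diagnostics.  On noisy, realistic data the first ridge is used.

**Permutation feature importance (PFI).**  The validation macro-F1 drop
when one feature column is shuffled, averaged over R = 10 seeded
permutations; a feature is retained when its mean drop is strictly
positive.  Permuting a constant column is the identity, so its drop is
exactly 0 by construction.

**Ensemble.**  The final set is the exact union of the two selections —
statistical robustness or empirical impact suffices.

*Behavior on synthetic data.*  Because the generator is separable by
construction, a baseline model is usually perfect on the validation
split; most single-feature permutations then change no prediction (drop
exactly 0) and the SHAP regression sits in the separation regime, so both
selectors degenerate and the union collapses to the handful of decisive
magnitude features (2–8 of 168 in our runs).  This is faithful selector
behavior on too-clean data, not a defect, but it means the union is *not*
a good deployment set here — refitting a fold on a 1-feature union cost
up to 0.2 macro-F1.  The pipeline therefore runs selection once as a
diagnostic stage (mirroring the select-then-train order of the original
protocol) and evaluates/deploys the full 168-feature model; per-fold
re-selection remains available in `cross_validate(selection_mode=...)`.
On real, noisy IMU data the union is expected to keep most features, and
the deployment choice should be revisited.

## Training and hyperparameter search

Backends: XGBoost (`xgb`), LightGBM (`lgbm`), CatBoost (`cat`), behind a
single fit/predict contract (softmax objective, K = 3, no early
stopping, single-threaded and seeded for bit-reproducibility).  The
`cat` backend raises an explicit environment error when the catboost
package is absent.  Search spaces are frozen to the published ranges
(e.g. learning rate log-uniform on [0.005, 0.30], 100–800 boosting
iterations, depth 3–10, row subsample [0.5, 1], column sample [0.3, 1],
min loss reduction [0, 5], per-backend leaf/child/regularization terms),
and the published per-backend optima ship as the `published-optimum` preset.

The Bayesian optimizer is a small seeded sequential model-based search:
parameters are mapped to the unit cube (log dimensions in log space),
the first min(10, n) trials are random, and later trials maximize
expected improvement under a Gaussian-process surrogate (Matérn 5/2 +
white noise, 256 random candidates per step).  The objective is the
macro-F1 of a weighted fit scored on an inner stratified 80/20 split.
Default budget: 25 trials in the demo pipeline, 50 in the API default.

## Evaluation

Macro metrics are one-vs-rest per-class quantities averaged with equal
class weight: accuracy, sensitivity, specificity, F1 and MCC; any
per-class term with a zero denominator contributes 0 (degenerate folds).
PR-AUC is average precision (step-function integration, no trapezoidal
interpolation), the conservative choice under imbalance; a class absent
from the truth is reported as missing, not 0.  Cross-validation is
stratified k-fold (k = 5) with augmentation applied inside each fold's
training portion only.  Model comparison across fold-level metrics uses
one-way ANOVA plus Tukey HSD at α = 0.05, with an all-equal guard
(F = 0, nothing significant).

**Lead time.**  The replay slides a stride-1 window over a test
recording, scores every window ending before the impact, and fires on
the first fall-labeled prediction (consecutive-window voting is
configurable, default 1).  Lead time is `impact − window end` in ms,
averaged over detected events per fall class; a fall with no firing
before impact counts as missed and is excluded from the mean.  Measuring
from the window end is the conservative convention — the classifier has
seen every sample it used.  By construction of the labeling rule the
expected lead approaches the critical-phase duration: ≈ √(2h/9.81) for
FFH (319–639 ms for the study heights 0.5–2 m), and the 0.25–0.6 s
critical duration for SLF.  Both exceed the 130 ms airbag inflation
margin with the detector behaving as trained.

**Latency** (ms per window) is wall-clock and hardware-bound; it is
reported with host metadata in the run manifest only, never compared,
and deliberately excluded from `report.json` so reruns are bit-identical.

## Synthetic data generator

The study dataset (48 subjects, 5991/1630/729 samples) is not deposited,
so the generator emulates the three classes at the SMV/orientation level:

* **Non-fall** (15 subtypes: 13 construction activities plus standing
  and walking): specific force about 1 g over a 4–6 s active segment;
  vibration subtypes add a 12–18 Hz component (0.2–0.35 g); hammering is
  a 2 Hz impulse train; jumps contain a crouch, a sub-0.5 g flight dip
  and a >2 g landing spike; bending/lifting tilt the gravity vector by
  20–25°.
* **SLF** (10 subtypes, critical durations 0.30–0.50 s): gait, then a
  linear tilt ramp to 50–70° about the subtype's axis with sustained
  angular rate θ_max/d (83–280 deg/s, well above any non-fall activity),
  SMV decaying from 0.85 toward 0.5 g, then a 3.5–5 g impact spike and a
  quiet lying posture.
* **FFH** (8 subtypes: forward/backward × heights 0.5/0.7/0.85/2.0 m):
  stance, then a free-fall phase of exactly `round(√(2h/9.81)·40)`
  samples with zero specific force (ballistic flight is gain-independent)
  and a tumbling rate of 80–200 deg/s, then the impact spike.

Additive Gaussian noise (σ = 0.03 g accel — 0.015 g for quiet standing —
and 2 deg/s gyro) and a per-recording movement-intensity gain
U(0.9, 1.1) applied to the dynamic (non-gravity) part of the signal give
the classifier a non-degenerate problem while keeping the rest level at
1 g.  Seeding is counter-based: each recording's seed derives from
(master seed, class hash, subtype hash, index), so changing the dataset
composition never reshuffles earlier recordings.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: biomechanical kinematics (joint dynamics,
active bracing), inter-subject signal morphology, sensor drift and
environmental artifacts, and above all the *overlap* between dynamic
construction activities and fall signatures that makes the real problem
hard.  The synthetic classes are separable by construction (mean critical
SMV: FFH < SLF < non-fall), so classification metrics here are upper
bounds that validate the pipeline's mechanics, not its field performance.

## Augmentation

Training windows are augmented (never test windows) with three
transforms per window at an intensity level L ∈ 1..4: jittering
(σ = 0.01·L g accel, 1·L deg/s gyro), scaling (one factor
U(1−0.05·L, 1+0.05·L) on all channels), and temporal warping (four
interior knots at 0.2/0.4/0.6/0.8 of the window displaced by Gaussian
σ = 0.05·L, monotone PCHIP time map, cubic resampling back to 40
samples).  The four-level scheme follows the cited augmentation
literature; the per-level magnitudes are package defaults since the
original values are not printed.  Default level: 2.

## Problem sizes and defaults

The demo pipeline (also what `scripts/acceptance.py` runs) uses
recording counts 600/160/72 — the study's class ratio scaled by 1/10 —
which yields roughly 2400/60/24 windows after non-overlapping
segmentation and critical-phase labeling, 5-fold CV, a 25-trial search,
and a 20 % recording-level holdout for the lead-time replay.  These
sizes keep a full run in a few minutes on one CPU while leaving every
class with enough windows per fold.  Fall recordings yield a fall window
only when a window boundary lands inside the critical phase (probability
≈ duration/stride ≈ 0.3–0.65), which is why window-level imbalance is
steeper than the recording-level ratio.

## Numerical choices and degenerate inputs

* Timestamps must sit on the 1/40 s grid within 1e−6 s; recordings are
  validated on read and write (files on disk are always valid).
* Numeric fields are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-identical.
* Argmax prediction breaks ties toward the lowest class index;
  class order is fixed (NON_FALL, SLF, FFH).
* Stratified splits use largest-remainder rounding so per-class test
  counts sum to `round(N·fraction)`.
* An empty selection falls back to the full registry (an empty feature
  set cannot be refitted); the union itself is reported unmodified.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; boosters run single-threaded with fixed
  seeds, making the full pipeline report bit-reproducible.

## Known limitations

Synthetic-only validation (see above); the `cat` backend is untested
against real CatBoost behavior in this environment; the SHAP regression's
ridge escalation makes its p-values conservative in the separation
regime; lead-time means depend on the subtype mix (height distribution
for FFH, duration distribution for SLF) and are reported with their
event counts for that reason.
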