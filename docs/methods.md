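# Methods

This note documents the models implemented in `limbintent`, the choices
made where the design was genuinely open, and what the synthetic test
conditions do and do not demonstrate.

## Signal model and preprocessing

Input is a time-synchronized 50 Hz stream (one record per 20 ms) of six
channels — Euler angles roll/pitch/yaw in degrees and gyro rates
ωx/ωy/ωz in degrees/s — for each of three body parts: upper arm, lower
arm, hand. Timestamps must advance by exactly 1/rate; all 18 channels must
be present at every timestamp. No unit conversion, sensor fusion or
calibration is performed.

Raw angle traces carry glitch-like noise, so every channel is smoothed
with a **centered moving-average filter**. The width is not dictated by
the method itself; the default is 5 samples (100 ms) — wide enough to
suppress single-sample glitches, narrow relative to the ≥ 1 s movement
episodes it must not blur. At the series edges the centered window simply
keeps the raw values that exist, so output length equals input length and
a constant series is a fixed point. Gyro channels are filtered with the
same width by default (`include_velocities=False` switches that off).

All windowing uses FIFO windows of **N = 10 samples** whose result is
attached to the last sample's timestamp — the causal convention for a
streaming recognizer. Segmentation uses stride 1 (one new result per
sample); state decoding uses stride 10 (one result per full window of new
samples). Both strides are parameters.

Per part, the **composite angular velocity** is Eᵢ = √(ωxᵢ²+ωyᵢ²+ωzᵢ²).
Window summaries: sample variance VAR (N−1 denominator), successive
differences SKEᵢ = Eᵢ₊₁ − Eᵢ, and range MN = max(E) − min(E).

## Motion-unit segmentation

A window is labeled from the maximum absolute adjacent-sample difference
of each of the 9 angle channels:

* all nine maxima < 0.3° → **static**;
* any maximum > 1.0° → **movement**;
* otherwise → **indeterminate**.

The 0.3°–1° band is genuinely undefined by the two rules above, so it is
resolved by hysteresis: an indeterminate window inherits the previous
resolved label, and a leading indeterminate run resolves to static
(dressing actions start with the arm at rest at the waist). The leading
N−1 samples, which precede the first window result, inherit the first
window's label. Thresholds are applied to the *filtered* angles — the
same signal the deltas are measured on; applying them to raw angles would
let unfiltered glitches open spurious movement segments.

Maximal same-label runs form alternating segments; an optional
minimum-duration filter (off by default) can absorb short segments into
their predecessor. Each movement segment is a **motion unit**; its
signature is the 9-vector of filtered-angle deltas between its boundary
samples, ordered (upper arm, lower arm, hand) × (roll, pitch, yaw). The
action feature vector is the concatenation of the first two units'
deltas (18 values). With fewer than two units the builder raises a
*not-ready* signal distinct from an invalid-input error: a streaming
caller waits rather than aborts.

Because window results attach to last samples, a detected movement
segment begins at the first sample whose window already contains a
super-threshold change — necessarily a sample at which some angle has
already moved. Delta anchors therefore carry a small systematic onset
offset; the synthetic generator is designed so this offset is negligible
(see below), and on real data it is bounded by one window of motion.

## Template classification

The distortion between test vector T and reference R of equal length M is
D[T,R] = Σ (tₙ−rₙ)², evaluated index by index — the diagonal (no-warping)
case of dynamic time warping, which is exact here because both vectors
have the same fixed length 18. If lengths ever differ, the shorter vector
is linearly interpolated onto the longer one's uniform index grid first;
this expansion was chosen over a dynamic-programming warping path because
the equal-length sum is defined as the diagonal sum, and the expansion is
isolated in one helper should a DP variant ever be wanted. Distances are
reported raw (no square root, no length normalization).

The predicted action is the argmin over the library; ties break in the
fixed order socks < shoes < laces. The runner-up-minus-best margin is
exposed so callers can reject low-confidence calls, but no rejection
threshold is applied by default. The bundled library holds one 18-value
template per action (reference deltas of the first two motion units,
mapped from the palm/forearm/shoulder naming of the source measurements
to hand/lower-arm/upper-arm). The magnitudes in the library are small
(≤ 1.7) relative to the degree-scale thresholds; the classifier only
requires that input vectors and templates share units, and the generator
treats the values verbatim as degree targets.

## GRNN state recognition

The motion state of the upper limb — acceleration (1), deceleration (−1),
static (0) — is predicted from four window features of the *hand's* E
series: [VAR, E_N − E₁, max E, min E]. The hand is the default source
because it is the most distal, highest-velocity segment; any part, or the
concatenation of all three, can be configured. The net change E_N − E₁
telescopes the SKE differences, and its sign separates acceleration from
deceleration; MN is recoverable as max − min and is not duplicated as a
fifth column.

The GRNN is standard Nadaraya–Watson kernel regression with a Gaussian
kernel and one isotropic smoothing parameter σ: training stores the
feature rows (standardized per column — VAR and the extrema live on very
different scales) and their numeric targets; prediction is the
kernel-weighted target average, computed with a max-weight shift so the
weights cannot all underflow (the σ→0 limit is then exactly the nearest
neighbour, and σ→∞ gives the target mean). Predictions are convex
combinations of {−1, 0, 1} and are decoded to the nearest label, with
exact midpoints (±0.5) rounding toward 0: preferring static is the
grasp-safe choice because a spurious motion call suppresses a command
outright, while a spurious static call can only fire one.

σ is selected by seeded k-fold cross-validation (k = 10): a seeded random
permutation is split into k near-equal folds; for each grid value the
mean held-out MSE of the *raw* regression outputs (not decoded labels) is
computed; the argmin wins, ties going to the smallest σ. The default grid
is 0.1–2.0 in steps of 0.1. On the clean, well-separated synthetic
datasets the smallest grid value typically wins; on noisier real data the
optimum moves into the interior of the grid.

## Grasp trigger

Reaching ends with deceleration into rest, so a command is emitted
exactly when the decoded state changes −1 → 0. The command toggles the
effector: the initial posture is open, the first trigger closes. A static
call directly after acceleration, or renewed acceleration with no
intervening static state, emits nothing; an acceleration state before
the deceleration is assumed, not verified. No debouncing or actuation
latency is modeled — those are device properties outside this package.

## Synthetic traces

The generator emulates the statistical structure the pipeline assumes,
not arm biomechanics. A script is an alternating sequence of *hold* and
*move* phases; canonical scripts for the three actions put the bundled
template deltas on their first two moves (so a generated action is
recoverable by the classifier), retrace them in later moves, and match
the expected socks decomposition of five holds and four moves; laces adds
one extra short adjustment move. Move phases last 1.0–1.2 s (≥ 50 samples
at 50 Hz), holds 1.6–2 s.

Within a move, each channel ramps to its net target along a smoothstep
(3u²−2u³). Because the net targets are ≤ 1.7°, such ramps alone could
never produce the > 1°-per-sample changes that define movement, so two
excursions are superimposed on the hand (a real hand sweeps far and
returns):

* a **closed circular excursion** of the roll/pitch pair, radius 8° by
  default, traversed with smoothstep timing after the onset swing — it
  returns exactly to its start (net deltas untouched) and its speed is
  unimodal, giving one acceleration and one deceleration run per move;
* an **onset jerk swing** on yaw: an antisymmetric down–up swing of ±4°
  over nine samples. Its purpose is detection timing: filtered with the
  default width-5 centered mean, the swing produces a > 1° filtered
  adjacent difference whose window closes at the swing's antisymmetry
  point, where the filtered yaw equals the hold value — so the detected
  segment start anchors on an undisplaced sample and the measured unit
  deltas land on the scripted targets (within ≈ 0.05° at default noise).

The gyro channels are the analytic derivative of the smooth profile
(ramps + circular excursion); the jerk swing deliberately appears only in
the angles, a physical inconsistency accepted to keep the analytic hand-E
reference unimodal per move. Hold angles jitter with clipped Gaussian
noise (σ = 0.05°, clipped at 2.8σ so adjacent differences stay below
0.28° < 0.3°); move targets get multiplicative overshoot (σ = 5%); gyro
channels get additive noise (σ = 0.5 deg/s). Generation asserts, per
phase, that holds respect the static rule and moves exceed the movement
rule, and raises an error naming the offending phase otherwise. One
seeded RNG drives each generation call; the seed is recorded in the
ground truth.

Ground truth per sample: the generating phase (hold → static segment,
move → movement segment), the state (0 in holds; the sign of the analytic
hand-E increment in moves), and each move's exact net delta vector.

The state-training dataset draws windows from generated single-grasp
traces (hold–reach–hold), keeping only windows that lie fully inside one
ground-truth state run — a window straddling a transition has no
well-defined label — and balances the three classes to within one row.

**What passing these conditions does not show:** the generator's holds
are cleanly below threshold and its moves cleanly above, its state runs
are long and its classes separable, so the near-perfect synthetic
accuracies are a correctness check of the machinery, not a performance
estimate for real volunteer data (where reported accuracies for
comparable pipelines are in the high-90s but below 100%). Sensor drift,
magnetometer disturbance, inter-subject variability and ambiguous
transition windows are all absent.

## Numerical conventions and degenerate inputs

* Indices are 0-based internally; CSV/JSON interfaces document 1-based
  ordinals only for motion units.
* Variance uses the N−1 denominator everywhere.
* Standardization guards constant columns (scale 1 after centering).
* Empty sequences, even filter widths, σ ≤ 0, fewer samples than folds,
  and decreasing timestamps raise `ValueError`; schema violations in
  files raise `SchemaError`; too-few motion units raise `NotReadyError`.
* Traces round-trip through CSV at 9 significant digits.
* All randomness (generator, CV folds, dataset sampling) flows through
  seeded `numpy` generators; identical seeds give bit-identical outputs.

## Problem sizes

The test suite and `scripts/acceptance.py` use: canonical traces of
~700–800 samples (≈ 15 s); 20 pipeline trials per action for the
recognition rate; 100 perturbed vectors per action (σ = 0.05) for
template recovery; a 1000-row state dataset with a 70/30 split and the
full 20-point σ grid for the GRNN experiment; 500 rows for the
brute-force CV cross-check; 100 random timelines for the grasp check.
These sizes make every stage's behavior measurable while keeping a full
run in the tens of seconds.
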