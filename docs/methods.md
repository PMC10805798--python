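# Methods

This note records the models, conventions and numerical choices behind
`myotune`, and what its synthetic experiments do and do not establish.

## Synthetic sEMG model

A recording session follows a fixed schedule: for each of `n_classes`
gestures (default 10) and `n_reps` repetitions (default 10), a contraction
of `contraction_s` seconds (default 6) is followed by `rest_s` seconds of
rest (default 4), sampled at `fs = 200` Hz on 8 channels.  Samples carry
the gesture id during contractions and the sentinel `REST = -1` otherwise.

During a contraction, channel `c` carries band-limited Gaussian noise — the
EMG-like carrier — normalised to unit RMS within the contraction and scaled
by `activation[k, c]`, the subject's per-class, per-channel amplitude.
The carrier band is 20–95 Hz: the dominant surface-EMG energy band
truncated below the 100 Hz Nyquist limit of the 200 Hz armband rate.
A trapezoidal envelope with a 250 ms rise/fall avoids unphysical step
onsets while leaving most of the contraction at plateau.  Sensor noise
(white, RMS 0.05 by default) is added throughout, and a 50 Hz powerline
tone of configurable amplitude can be injected to exercise the notch
filter.  Repetitions are grouped by class by default; a seeded randomised
order is available.

Subjects are drawn by `make_subject_model`: activation rows are
`1 + separability · d[k, c]` with `d ~ U(-0.75, 0.75)` fixed by the seed,
so `separability ∈ [0, 1]` directly scales how far apart class patterns
lie (0 makes all classes identical).  Units are arbitrary; the generator
does not model motor-unit physiology, electrode shift, fatigue or
inter-session variability.  Consequently the class information is carried
almost entirely by the per-channel amplitude pattern — a deliberate
simplification with consequences for augmentation (below).

All generation is bitwise deterministic given `(model, protocol, seed)`.

The session length follows the schedule arithmetic
`n_classes × n_reps × (contraction_s + rest_s) × fs` — 1000 s (200 000
samples) per subject under the defaults.

## Preprocessing

- **Notch filter**: second-order Butterworth band-stop centred at 50 Hz.
  Only order and centre frequency are fixed by convention; the −3 dB
  bandwidth is set to 4 Hz (Q ≈ 12.5), which removes the powerline tone by
  hundreds of dB while leaving 10 Hz essentially untouched (< 1 dB).
  Filtering is causal single-pass (no zero-phase compensation), matching a
  real-time control constraint.
- **Windowing**: window length in samples is `round(window_ms · fs / 1000)`
  and the overlap step is `max(1, round(w · (1 − overlap)))`, so the
  studied grids (100–350 ms; 20–80%) are exactly representable at 200 Hz
  (200 ms → 40 samples; 80% → step 8).  Disjoint counts are `⌊L/w⌋`,
  overlap counts `⌊(L−w)/s⌋ + 1` for `L ≥ w`; both are verified against a
  brute-force start-index enumerator.  Windows are computed per
  contraction repetition and never cross repetition boundaries, so no
  window mixes labels or contains rest.
- **Augmentation**: training images are randomly flipped and translated
  with zero fill (up to 4 px per axis).  "Vertical-axis" flipping is
  interpreted as time reversal (mirror about the vertical axis);
  channel-order reversal is available as `flip_axis="channel"`.  A
  `shift_axes="time"` mode restricts translations to the time axis: on the
  synthetic data the class is channel-coded, and channel shifts would
  destroy exactly the feature that defines the class, so the desk-scale
  experiments use time-only shifts.  On real recordings, where temporal
  structure also discriminates, both-axis shifts are the appropriate
  default.  Augmentation touches training batches only.
- **Splitting**: stratified 70/20/10 by largest-remainder allocation per
  class, seeded.  Stratification guards against empty-class test sets at
  small scale.

## CNN classifier

The network has 3 sections of `section_depth` identical blocks (3×3
same-padding convolution → batch normalisation → ReLU), a 1×2 max-pool
along the time axis after each of the first two sections (the channel axis
has only 8 rows), and a dense softmax layer.  Total conv layers:
`3 · section_depth`.  Filters per block in section `k` are
`round(base_filters · 2^(k−1) / √section_depth)`, which keeps the total
parameter count within ×1.5 across depths 1–3 so that depth is a shape,
not a capacity, knob.

Training is SGD with momentum (`v ← μv − η∇`, `w ← w + v`) and an L2
penalty added to convolution and dense kernel gradients (batch-norm
parameters and biases are not penalised).  The best validation-CER epoch's
weights are kept; early stopping triggers after `early_stop_patience`
non-improving epochs.  Default budget is 50 epochs with patience 10,
conservative for the full-scale task; the desk-scale studies shorten this
(below).

Batch normalisation uses the statistics of the batch being processed, at
training *and* evaluation time; evaluation is always a single pass over the
full set.  This makes prediction a pure, deterministic function of the
weights and the evaluated data — training with a zero learning rate leaves
both weights and measured error exactly unchanged, and identical seeds
reproduce identical histories bit for bit.  The cost is that single-image
prediction is not meaningful (statistics would degenerate) and that a
prediction depends weakly on the composition of the evaluated set; for the
set-level error rates studied here this is immaterial.

Error is the classification error rate (CER), the fraction of
misclassified images, with a Wilson score 95% interval (a symmetric Wald
interval is available behind a flag).  Wilson is used because test splits
at desk scale are small and error rates near 0 are common, where Wald
degenerates.

## Bayesian optimisation

The objective is the validation CER of a trained model as a function of
four hyperparameters; all modelling happens in the unit cube after
log-scaling the learning rate and L2 strength and linearly scaling
momentum; section depth is decoded by rounding to the nearest feasible
integer.

- **Surrogate**: GP with anisotropic Matérn 5/2 kernel, fitted by
  maximising the log marginal likelihood with L-BFGS-B from a default
  start plus 2 seeded random restarts, on standardised targets.  Bounds:
  length scales in [0.03, 30], amplitude in [1e-3, 10], noise std in
  [1e-4, 2] (standardised scale).  Cholesky failures escalate jitter
  (×100 from 1e-10, 8 attempts) before raising a conditioning error.
- **Incumbent**: the *lowest posterior mean over evaluated points*, not
  the minimum observed target — with a noisy objective the posterior mean
  is the defensible summary of what has been seen.
- **Acquisition**: closed-form expected improvement
  `δΦ(δ/σ_F) + σ_F φ(δ/σ_F)`, `δ = incumbent − μ`, maximised over 2048
  scrambled Sobol candidates followed by coordinate-wise local refinement
  of the top 5 (3 passes of ±0.1/0.03/0.01 steps).  If every candidate has
  zero EI the proposer falls back to the maximum-σ_F point and logs the
  event.  EI-per-second divides EI by a positive predicted cost from a
  second GP fitted to log evaluation time (exp-transformed posterior mean,
  floored at 1 ms); it is available but EI is the default, since the
  studied budgets are evaluation-count-, not time-, limited.
- **Over-exploitation control**: a winning proposal with
  `σ_F(x) < σ · t_σ` (exploration ratio `t_σ = 0.5` by default; no
  canonical value exists) is deemed over-exploiting.  The kernel's
  inverse-length-scale (roughness) components are then multiplied by the
  iteration count — equivalently the length scales shrink — which raises
  the posterior variance between observations, and the proposal is redone
  from the inflated surrogate, at most 3 times per iteration.  Scaling the
  *amplitude* or growing the length scales would lower, not raise,
  between-point variance, which is why the rescaling is pinned to the
  roughness components.
- **Loop**: 4 seeded Sobol points as the initial design, then
  fit → propose → evaluate to the budget (default 30 evaluations).
  Objective exceptions are recorded as failed evaluations with target
  `worst + 3·spread` so the surrogate learns to avoid the region.  The
  whole trace is deterministic given the seed.

Random search draws each dimension on its own scale (log-uniform,
uniform, uniform-integer); grid search evaluates an explicit grid
(default 5 learning rates × 3 momenta × 7 L2 values × 2 depths = 210
points) after validating every value against the bounds; manual search
evaluates one empirically chosen point.  All strategies consume the same
objective callable and emit the same trace type.

## Desk-scale study conditions

The synthetic experiments run with 5 subjects at separability 0.8, sensor
noise RMS 0.2 and powerline amplitude 0.2, on a shortened protocol of
3 repetitions × (3 s contraction + 1 s rest), and a slimmed training
recipe: `base_filters = 6`, batch 24, at most 10 epochs with patience 2,
per-class training caps (48 images for the segmentation sweep, 24 for the
optimisation objective) and a per-class validation cap of 16.  These sizes
were chosen once so a full sweep-plus-HPO study completes in minutes on a
single CPU while every qualitative contrast of interest (overlap vs
disjoint windowing, tuned vs manual hyperparameters, generalised vs
per-subject configurations) remains visible; they are function arguments,
not constants baked into the pipeline.

Under these conditions the observed orderings are stable: overlapped
200 ms windows beat disjoint ones for every subject (roughly 0.09 vs 0.24
mean test CER), budget-30 Bayesian optimisation beats the fixed manual
configuration by a wide margin (≈0.03–0.05 vs ≈0.37 — the manual
configuration's L2 strength of 0.0939 is punishing for a small network on
little data), and the generalised configuration lands within a few
hundredths of the per-subject optima.

## What the synthetic experiments do and do not show

Passing tests establish that the pipeline is internally correct (oracle
agreement for EI, GP posterior, window counts, filter response), that the
optimiser finds minima of known objectives more efficiently than random
search, and that the study-level orderings hold on data whose class
structure the generator controls.  They do not certify error rates on real
sEMG: real recordings have temporal gesture dynamics, non-stationarity,
electrode-shift and inter-subject variability that the generator omits,
and real CER levels depend on training at full scale.  The published
20-subject tables bundled in `myotune.reference` are used as inputs to the
aggregation utilities, not as targets the synthetic pipeline is expected
to reproduce.

## Degenerate inputs and tie-breaks

- A session with only rest raises a distinct `AllRestError`; a segment
  shorter than one window yields an empty window set, and a sweep
  condition with no windows is recorded as missing (NaN) without aborting
  the run.
- Ties in the generalised section-depth mode break toward the smaller
  depth (cheaper model).
- ANOVA with zero within-group variance raises a degenerate-case error
  when the means are equal and returns `F = ∞, p = 0` otherwise.
- CER confidence intervals clamp exactly to 0/1 at empty/full error
  counts.
- The timing model floors predicted cost at 1 ms and counts floored
  events.
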