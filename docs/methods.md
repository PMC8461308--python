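# Methods

## The virtual patient

Clinical glove recordings are not public, so every pipeline stage is
exercised against a generative stand-in. A patient is a small parameter
vector; a session is a deterministic function of (patient, session config,
seed).

**Tremor signal.** Each gyroscope axis carries a sinusoid at a
patient-specific dominant frequency with an independent uniform phase,
plus additive white Gaussian sensor noise:

```
g_a(t) = m(t) · A_a · sin(2π f_a t + φ_a) + ε,   A_a = baseline_rms_a · √2
```

Cohort summaries of this kind of data report only per-axis RMS and a
dominant frequency, both of which a noisy sinusoid reproduces; this is the
simplest generator matching all measured summaries. The generator does
**not** emulate amplitude modulation within a session (baseline is
stationary), harmonics, movement artifacts, axis cross-correlation, or
EMG/stimulation artifacts in the gyroscope channel. A green test therefore
establishes that the estimators recover the parameters of *this* signal
family; it says nothing about robustness to nonstationary clinical tremor.

**Suppression envelope** `m(t)` is piecewise: 1 at baseline; once the
applied pulse amplitude reaches the patient's `response_threshold` it slews
linearly to `suppression_floor` over 0.5 s (physiological smoothing; the
0.5 s value is immaterial for 1-s aggregates); after withdrawal it holds
the floor for `reset_hold` seconds and then returns linearly to 1 over
`reemergence_ramp` seconds. The re-emergence shape is unknown in reality;
linear is the one-parameter choice. Closed forms for the reduction
durations follow directly from this envelope and are used as ground truth
in tests (`expected_reset_summary`).

**Default distributions** (`CohortSettings`): per-axis frequency
truncated-normal 5.5 ± 1.7 Hz on (2.5, 11); per-axis baseline RMS
log-normal moment-matched to means (13.2, 16.0, 8.3) with SDs ~1.5–2× the
mean (cohort RMS distributions are strongly right-skewed);
`response_threshold` truncated-normal 9.45 ± 4.29 mA on [3, 17];
`suppression_floor` uniform (0.1, 0.4) — below 0.4 so that effective
stimulation can satisfy both the 50 % reduction criterion and the 2.5×
stopping rule; `reset_hold` log-normal with median ≈ 100 s (the
post-withdrawal reduction statistic is strongly right-skewed with values
from 0 to ~17 min); `reemergence_ramp` uniform 10–40 s; noise SD 5–15 % of
the mean baseline RMS. Sampling rate defaults to 50 Hz (unstated for the
real device; all windowing is rate-agnostic, minimum 25 Hz for Nyquist).

**Protocol.** The manual session is emulated as ~5 min baseline, then
1 mA amplitude steps every 10 s until the response threshold is reached,
~30 s of continued stimulation, switch-off, and up to 10 min of
post-stimulation recording. Explicit per-second amplitude schedules are
also accepted.

## Features

Windows are non-overlapping, half-open `[k, k+1)` s, anchored at session
start; the trailing partial window is dropped. Per-window pulse amplitude
(and section label) is the modal within-window sample value with ties
broken toward the later sample — under the 10-s dwell protocol an
amplitude change inside a 1-s window is rare, and when it happens the
later value describes the commanded state. No detrending is applied before
RMS (a resting gyroscope is zero-mean by construction); mean removal is
available for real logs via the periodogram's constant detrend. Dominant
frequency is the periodogram argmax in (2, 12) Hz, zero-padded to ≤0.125 Hz
bin spacing (twice as fine as the ±0.25 Hz recovery tolerance used in
tests).

## Reset-time metric

* Baseline: per-axis **median** RMS over the before section (≥30 windows),
  robust to occasional artifact windows.
* Reduction: 3-axis RMS magnitude below 50 % of baseline magnitude. The
  published criterion does not name an axis combination; the magnitude is
  the rotation-invariant choice. The 2.5× stopping rule, by contrast, is
  stated for the x and y axes specifically and is implemented exactly so.
* Persistence: entry to and exit from the reduced state require 3
  consecutive qualifying windows (rejects single-window noise at 1-s
  resolution), attributed retroactively to the start of the run.
* Re-emergence: magnitude at or above 75 % of baseline for the persistence
  window. "Re-emerged to the pre-stimulation level" fixes no threshold;
  75 % balances noise immunity against censoring. Configurable.
* `C` counts reduced windows between stimulation off and re-emergence
  onset; if the tremor never re-emerges before the session ends the
  summary is flagged `censored` (not an error). `D = B + C` holds by
  construction and is asserted on every summary. The additive definition
  (excluding the pre-reduction ramp time from D) is the one consistent
  with published cohort means, where the during-stimulation and
  after-withdrawal components sum exactly to the reported reset time.
* UPDRS-based clinical reduction criteria are outside the package's scope:
  a clinical rating can be supplied externally but is never computed.

## Labelled dataset

Class map: 0 → 0, 1–5 → 1, 6–10 → 2, 11–15 → 3, ≥16 → 4 mA; non-integer
amplitudes are floored first (the protocol uses integer steps; the floor
guards real logs). `prev_class` is the observed previous window's class
(teacher forcing), padded with 0 at sequence start. Record filtering
removes during-section windows where tremor is present yet the amplitude
is zero — the footprint of manual mid-exploration switch-offs, which are
contradictory training examples ("tremor present, stimulate at 0 mA").
The filter reuses the 50 % reduction criterion and logs every removal;
clean simulated sessions produce zero removals. Folds are patient-wise:
patients are shuffled by seed and split as evenly as possible (20 patients,
k=3 → 7/7/6); fold summaries recompute percentages from counts.

## Models

* Features: `gyro_only` = (RMS_x, RMS_y, RMS_z); `gyro_plus_prev` adds
  I_{t−1} as a numeric input.
* Standardization (fit on training folds only) for SVM, NN and LSTM; none
  for logistic regression and random forest.
* Defaults: LR library defaults (baseline model, no grid); RF 100 trees,
  bootstrap, √p features; SVM RBF with C = 1; NN two hidden layers of 100
  (ReLU, Adam). Grid search is exhaustive over the documented ranges
  (RF 120 candidates, SVM 12, NN 36), selected by macro-F1 on an inner
  2-fold patient-wise split of the training folds — the original
  experiment does not describe its inner validation; a grouped inner
  split is the choice that preserves the no-leakage property cheaply.
* LSTM: two layers of 100 units, time-distributed softmax head, Adam at
  lr 0.001, categorical cross-entropy, implemented in NumPy and verified
  against numerical gradients. Sequences are per-patient chronological
  chunks of 60 windows with state reset at chunk boundaries; training
  defaults are 60 epochs with batches of 8 chunks (enough updates to
  converge on desk-scale cohorts). Evaluation resets the recurrent state
  every 60 steps to match training — carrying state beyond the trained
  horizon was measured to drift. Teacher forcing is used in both training
  and evaluation, mirroring the data-collection protocol; the closed-loop
  controller instead runs free (previous *predicted* class), which is
  exactly the deployment gap the offline evaluation cannot see.
* Metrics: per-class one-vs-rest P, R, F1 with 0/0 := 0; macro averages
  are unweighted means over classes **present in the fold's true labels**
  (a fold can lack the rarest class entirely; absent classes are logged
  per fold rather than averaged in as zeros). Accuracy = trace/total;
  per-class accuracy = diagonal/row-sum (NaN when absent). Reports carry
  per-fold values, mean ± SD, and the relative improvement (%) of
  `gyro_plus_prev` over `gyro_only`.
* Determinism: one seed per `ModelSpec`; identical seeds give identical
  predictions. Single-class training data yields a flagged constant
  predictor instead of a crash.

## Closed-loop controller

One decision per 1-s window. The model receives (RMS_x, RMS_y, RMS_z,
previous *predicted* class); the commanded amplitude moves toward the
predicted class's maximum (0/5/10/15/20 mA) by at most 1 mA per step, with
a configurable dwell (default 10 steps, reproducing the manual 10-s ramp
cadence) between increments. At stimulation onset the controller captures
the window's RMS as the reference for the 2.5× stopping rule; when the
rule fires the command drops to 0 (a configurable hold, default 0 s, can
reproduce the manual ~30 s continuation). The switch-off is the one step
exceeding 1 mA — it is the protocol's own "turn off the EMS". Once
stopped, the controller stays stopped for the session; no re-arm policy is
defined for the original experiment, and remaining off is the conservative
reading. The patient side of the co-simulation uses the same envelope
dynamics as the open-loop simulator, stepped window by window, so
session-metrics ground truth carries over. With a noise-free patient the
criterion fires iff `suppression_floor ≤ 1/2.5`; both sides of that
boundary are tested.

## Statistics

* Wilcoxon signed-rank: zero differences dropped; for ≤25 usable pairs the
  exact null distribution is computed by a dynamic-programming convolution
  over doubled midranks (equivalent to enumerating all 2^n sign patterns,
  and valid under tied magnitudes); otherwise the normal approximation
  with tie correction. Two-sided p = 2 × min tail, capped at 1. The
  unpaired Mann-Whitney variant is available separately.
* Spearman: midranks, t-approximation p; constant inputs are flagged
  degenerate.
* Stepwise OLS: forward entry at p ≤ 0.05, backward removal at p ≥ 0.10
  (the conventional defaults of mainstream stepwise tooling), constant and
  exactly collinear candidates dropped with a warning list; an empty
  selection returns the intercept-only model. Selection is invariant to
  candidate ordering when entry p-values are distinct.
* `predict_reset_time` evaluates a fitted (or the published) linear model;
  negative predictions are floored at 0 and flagged — a linear model with
  a negative intercept extrapolates below zero for small E and A, where a
  negative duration is meaningless.

## Known limitations

* The generator's stationary baseline and noise-free class structure make
  the prediction task easier than clinical data; published real-data
  scores are not reproduction targets (the recordings are unavailable),
  and synthetic results should be read as pipeline verification, not as
  clinical performance estimates.
* The tremor model has no within-session drift, no re-emergence overshoot,
  and no pain/tolerance constraints on stimulation.
* The controller assumes the 1-s feature cadence is fast enough; real
  devices may need faster loops and actuator latency modelling.
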