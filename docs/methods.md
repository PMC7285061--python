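# Methods

## Pipeline overview

The package infers seated acute stress from three wearable streams: a
16-channel plantar-pressure insole (50 Hz), a 3-axis ankle accelerometer
(50 Hz) and, in field mode, a 3-axis wrist accelerometer (32 Hz). The
unit of analysis is the non-overlapping 10 s window; all modelling is
two-class (stress vs relaxation).

Assumptions baked into the design:

* the wearer is seated during every window the classifier judges (the
  field pipeline enforces this with a posture gate; the lab pipeline
  assumes it by protocol);
* timestamps are authoritative and nominally uniform — streams whose
  median inter-sample gap deviates more than 10 % from the nominal rate
  are rejected rather than resampled;
* pressure values are raw non-negative sensor units; accelerometer
  values are in g with gravity left in.

## Windowing and filtering

* `window_s = 10` — at 50 Hz a full window holds 500 samples. A window
  is emitted only if it contains ≥ 90 % of its nominal sample count;
  windows are anchored at the segment (lab) or stream (field) start and
  the trailing partial window is dropped.
* `ma_span_s = 1` — pressure channels are smoothed with a **trailing**
  (causal) 1 s moving average before any summation. Causality keeps the
  filter stream-compatible; the induced ~0.5 s lag is immaterial against
  the 10 s window. Accelerometer channels are deliberately left raw:
  the posture features are plain means (unaffected by smoothing) and the
  tapping features need the unsmoothed oscillation energy.
* `trim_s = 60` — in training mode the first and last 60 s of every task
  are discarded (task accustomisation and exhaustion); segments not
  strictly longer than 120 s are excluded entirely.

## Features

* **A1/A2/A3** — window means of the forefoot (sensors 1–12), rearfoot
  (13–16) and total pressure sums. A3 ≡ A1 + A2 holds exactly.
* **B1/B2 (CoP)** — rear-weighted average of sensor coordinates with
  `rear_weight = 3`, implemented exactly as the weighted form prints;
  the weighting plausibly compensates the 12-vs-4 sensor count but no
  derivation is claimed. The CoP is computed from the **window-mean**
  channel values; a per-sample mode (CoP per sample, then averaged) is
  available via `per_sample=True` — the two orders differ for
  time-varying load and the window-mean order is the default contract.
  Windows with zero total weighted pressure have no CoP and are dropped
  with a logged reason. For any non-negative load the CoP lies in the
  convex hull of the sensor coordinates and is invariant to uniform
  pressure scaling.
* **C1–C3** — per-axis raw window means. Gravity is not subtracted:
  its projection is the leg-angle signal.
* **D1/D2** — the three candidate 3-D norms (one axis inverted each,
  `a_inv = 2·max(a) − a`, max taken within the window) are ranked by
  peak-to-peak; ties break in axis order X → Y → Z. The winner (V3D)
  is mean-removed and a rectangular-window one-sided periodogram taken.
  D2 is the frequency of the maximum-power bin at or above
  `min_freq_hz = 0.5` (power ties break toward the lower frequency);
  D1 is the smallest frequency at which cumulative power over the
  searched bins reaches half their total. The 0.5 Hz floor keeps
  postural drift near DC from posing as a tapping frequency; it is
  configurable. A window that is constant after detrending returns
  D1 = D2 = 0 and is flagged.

## Modelling

* Ground truth keeps only unambiguous task blocks: stress tasks with a
  self-rating > 4 and relaxation tasks with a rating < 4 on the 1–7
  scale; a rating of exactly 4 is always excluded, as are unrated tasks.
* The classifier is two-class LDA with pooled within-class covariance
  and empirical priors. Features are z-scored with training-set
  statistics — the ten features mix raw pressure units, millimetres,
  g and Hz, so multi-feature models need a common scale. A singular or
  ill-conditioned pooled covariance receives a trace-scaled ridge
  (λ = 1e-6 · tr(Σ)/k), logged. An exact posterior tie predicts relax
  (the conservative direction for a stress detector).
* Validation is leave-one-user-out. Accuracy is the percentage of
  correctly classified 10 s windows **per user**, then averaged across
  users (the reported SD is across users, ddof = 1); the accuracy curve
  indexes windows by their position within each task and averages across
  users. Every fold asserts train/test participant disjointness from row
  provenance and raises on violation. Separation sharpness is a
  two-sided paired t-test on per-user predicted-stress fractions under
  the two conditions; all-zero differences report p = 1, constant
  nonzero differences report p = 0 with a divergent t, and fewer than
  three paired users is flagged undefined.

## Field mode

* AVC is implemented as the mean absolute successive difference of the
  acceleration-vector magnitude per unit time,
  AVC = Σᵢ |‖vᵢ₊₁‖ − ‖vᵢ‖| / T in m s⁻³ (inputs in g are converted with
  g = 9.80665 m s⁻²), over 5 s windows. The decision bands are walking
  ≥ 2, standing < 0.1, sitting 0.1–0.2. The band [0.2, 2) belongs to no
  class and maps to an explicit `unknown` label that never enters the
  sitting mask — silently widening a band would change the stated rule.
* A 10 s foot window counts as sitting only if fully contained in a
  sitting interval (partial-overlap gating available by flag). Hours are
  anchored at the stream start; a trailing partial hour is reported but
  flagged. R_S is undefined (NaN, flagged) for hours without sitting
  windows; the SRSL–R_S Pearson correlation is flagged undefined with
  fewer than three valid hours or zero variance in either series.
* The EDA utility computes per-10 s means and least-squares slopes of a
  4 Hz electrodermal stream; it is a validation aid, not a classifier
  input.

## Synthetic data

The generator emulates the study conditions end to end; its defaults are
the bench every test and the acceptance script run against.

* **Lab sessions**: ten alternating 320 s stress/relax tasks, i.e.
  200 labelled windows per participant after trimming. Per-user
  heterogeneity: baseline total load ~ N(200, 15) raw units, forefoot
  share ~ U(0.55, 0.65), resting leg angle jittered around
  (0.15, 0.15, ≈0.97) g, tapping propensity a power-jittered version of
  the profile's `tap_prob` (exact at 0 and 1 so single-signature
  ablations stay deterministic).
* **Stress signatures** (all individually switchable, magnitudes chosen
  for clear separability — they are design choices, not measurements):
  forefoot gain 1.5×; anterior CoP shift 15 mm, realised as a pressure
  transfer toward each region's front sensor row that preserves the
  forefoot and rearfoot sums (so the gain signature stays clean; the
  attainable maximum with the bundled layout is ≈ 21 mm and requests
  beyond it are capped, with the realised shift recorded in the truth
  record); leg-posture change of −0.3 g on Z (+0.15 g on X); tapping at
  4 ± 0.3 Hz, amplitude 0.05 g, present in 70 % of stressed windows.
* **Noise**: white Gaussian, pressure SD 0.5 raw units per channel and
  accelerometer SD 0.003 g — the latter matching the ~1.5–3 mg RMS noise
  of consumer IMU accelerometers at a 25 Hz bandwidth.
* **Field days**: 8 × 3600 s hours; seated bouts of 2–8 min alternate
  with standing/walking bouts sized to a planted sitting fraction
  (default 0.795). Within seated time each 10 s window is stressed with
  probability equal to its hour's intensity; the hourly self-report is
  1 + round(6·intensity) ± 1 Likert step (jitter configurable, 0 for
  degenerate-case tests), clipped to [1, 7]. Wrist windows carry planted
  AVC values drawn inside the correct posture band, realised as a
  square-wave modulation of the acceleration magnitude. Broadband wrist
  noise is deliberately omitted: the sitting band is only 0.1 m s⁻³
  wide, and any visible white noise adds O(rate·σ) to the
  mean-absolute-difference AVC, which would misstate the planted label.
* The bundled insole layout is a synthetic stand-in (plausible UK 9–10
  geometry, documented in the file); every CoP computation takes the
  layout as a parameter so measured layouts substitute directly.
* Determinism: all randomness flows from one integer seed through
  numpy's PCG64 `default_rng`; fixed seeds give bit-identical streams.

**What passing tests do not show.** The generator's stress windows are
piecewise-stationary with clean, additive signatures and compliant
self-reports; real seated-stress data has drifting baselines, partial
and idiosyncratic signatures (not every wearer taps), posture changes
uncorrelated with stress, sensor creep and rating noise. Perfect LOUO
accuracy on the default profile therefore validates the pipeline's
mechanics and calibration (chance under the null, monotone in effect
size), not field-grade detection performance.

## Known limitations

* Binary stress/relaxation only; no intensity scale beyond R_S.
* No resampling of irregular streams; out-of-tolerance streams are
  rejected, not repaired.
* The AVC formula is one defensible reading of "first derivative over
  the window"; alternatives (e.g. per-axis derivatives) would need the
  thresholds re-examined.
* EDA support is summary statistics only — no artefact correction or
  decomposition.
* Only LDA is implemented; the surface admits other classifiers but none
  are provided.
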