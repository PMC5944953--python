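# Methods

This note documents the models, estimators, calibrations and numerical
choices behind `gaitlds`, in the order data flows through the pipeline.

## Signal preprocessing

**Startup trim.** The first 300 samples of every channel are discarded
(sensor settling). Configurable via `LdsConfig.startup_samples`.

**Heel-strike detection.** Foot contacts are identified on the
anterior–posterior (AP) trunk acceleration: the signal is low-pass filtered
at 20 Hz (4th-order Butterworth, zero-phase `filtfilt`, so peak times are
not shifted), the step rate is estimated from the dominant spectral peak in
1.0–3.4 Hz, and positive peaks exceeding 0.3 × the rolling peak amplitude
(≈3-step window) that precede a positive-to-negative zero crossing are taken
as contacts. Both feet produce contacts; every second contact is a
same-side heel strike, i.e. one stride. The detector cannot know which foot
is the reference side, so stride-level outputs carry a parity ambiguity of
one step; tests compare against ground truth under both parities. All
downstream analysis runs on the *unfiltered* signal — filtering exists only
inside event detection.

**Turn excision.** Walking protocols in a corridor include U-turns, which
are not steady-state gait. For each annotated turn interval, the strides
overlapping it plus one full stride before and one after are removed;
segment boundaries snap to heel strikes. Turns are expected to be annotated
(the protocol marks them); an unannotated recording passes through as one
segment.

**Stride selection and resampling.** The first 150 straight-walk strides
(configurable to the middle 150) are concatenated and the whole series
mapped onto a uniform grid of 150 × 100 = 15,000 points with a cubic spline
(linear by configuration). Because strides vary in duration, each stride
receives ≈100 points rather than exactly 100; this preserves the natural
temporal structure instead of time-normalizing each stride individually.
The map is the identity on input already sampled at 100 points per stride.

**Stride frequency** is the dominant peak of the zero-padded FFT amplitude
spectrum of the AP trunk signal within 0.5–1.5 Hz (resolution ≤ 0.01 Hz).
The spectrum is taken on the concatenated straight-walk samples when
segments are available, because turn intervals blur the rhythm. A peak must
exceed 5 × the in-band median amplitude; otherwise there is no walking
rhythm to report and the call fails. The 0.5–1.5 Hz band brackets the
elderly-gait stride rates the cohort tables contain (~0.90–1.02 Hz).

## State-space reconstruction

**Delay (τ).** First local minimum of the average mutual information (AMI),
estimated with an equiprobable-bin histogram (⌈N^(1/3)⌉ bins, edges at
quantiles of the series), in bits. The strict three-point minimum rule is
the default; `window=k` requires the minimum to dominate ±k lags, which
rides over estimator noise on the shallow AMI floors of nearly periodic
signals (used with k = 3 when delays are computed per subject).

**Dimension (d).** Global false nearest neighbours with the standard Kennel
thresholds rtol = 15, atol = 2, and a 1% false-fraction criterion.

**Cohort default.** The pipeline's default mode applies one fixed parameter
set to every subject — delays (samples at 100/stride) trunk V/ML/AP =
11/8/10, shank = 9/6/11, dimension 6 — matching how the reference cohort
was processed; per-subject computed parameters are available via
`LdsConfig(embedding="computed")`. Fixed parameters keep the metric
comparable across subjects; per-subject parameters track individual
attractor geometry at the cost of comparability.

## Rosenstein Lyapunov estimation

For each embedded state, the Euclidean-nearest neighbour with temporal
separation greater than one stride (100 samples — the mean-period Theiler
rule) is found with a k-d tree; an exact quadratic-time search is kept as a
test oracle and the fast path must match it exactly. The divergence curve
is the mean of ln‖**X**(i+k) − **X**(j+k)‖ over pairs, averaging at each
horizon only the pairs still inside the series (shrinking mean; a
fixed-pair-set alternative would discard most references on 150-stride
records). Distances are floored at 1e-12 before the log so exact clones
produce a flat curve rather than −∞; slopes are unaffected.

- stLE = least-squares slope over t ∈ [0, 0.5] strides (one step), both
  endpoints inclusive on the sample grid;
- ltLE = slope over t ∈ [4, 10] strides;
- units: ln-divergence per stride (divide by stride duration for per-second
  rates).

Scaling the input by any positive constant shifts the curve by a constant
and leaves both slopes unchanged (tested).

**Validation against an independent oracle.** On the Lorenz system (σ = 10,
ρ = 28, β = 8/3; x-component, dt = 0.01, N = 15,000, d = 3, τ from AMI,
Theiler = one mean period from the amplitude-weighted mean frequency), the
divergence-curve slope over the post-transient linear region t ∈ [0.8, 2.5]
time units agrees with a Benettin tangent-space exponent (RK4 variational
integration, per-step renormalization; ≈0.90 nats per time unit) within
15%. The first ~0.8 time units of the curve are excluded from the fit: the
early transient reflects the geometry of the initial neighbour offsets, not
the exponent. The Benettin routine shares no code with the Rosenstein path.

## Synthetic gait signals

`simulate_gait` is a harmonic-plus-jitter construction, not a biomechanical
simulator: it provides ordered, tunable local instability with known ground
truth, which is what the tests require.

- Stride-locked harmonics: the medial–lateral axis oscillates at the stride
  frequency, AP and vertical at the step frequency, plus a stride-locked
  asymmetry component (default 0.18 of the fundamental) on AP/V — the
  left/right asymmetry that makes the stride line visible in an AP
  spectrum. ML carries five harmonics so that its AMI first minimum falls
  in the 6–12-sample band where real trunk ML delays live.
- Per-stride jitter: stride durations and amplitudes are scaled by
  1 + N(0, `perturbation_sd`) — the local-instability dial. Downstream stLE
  increases strictly with it (tested over {0.01, 0.05, 0.1, 0.2}).
- Defaults mirror the protocol the cohort tables describe: 296.3 Hz
  sampling, stride frequency 0.955 Hz, ~5 minutes (285 strides), a 2-stride
  U-turn every 19 strides (≈25 m at typical elderly stride length), a
  startup transient decaying within the 300 trimmed samples, and white
  sensor noise (0.03 m s⁻²).
- Ground truth (heel-strike times, step times, turn intervals) is exported;
  one seeded generator per call, bit-reproducible.

What the generator does *not* emulate: gravity projection and sensor tilt,
soft-tissue artefacts, amplitude drift with fatigue, pathological gaits,
missing data. Passing tests therefore show the estimators recover known
structure from realistic-looking quasi-periodic signals; they do not certify
performance on arbitrary clinical recordings.

## Synthetic cohort and its calibration

`simulate_cohort` produces per-subject tables with the three prospective
fall groups. Defaults are calibrated to the reference elderly cohort this
package models:

- group sizes 81 / 35 / 15 (N / F1 / F2+), hence a multiple-faller fraction
  of 11.5%;
- demographics per group moment-matched to the published means and SDs
  (age, height, weight; BMI derived), so cohort-level moments are exact by
  construction rather than subject to √n sampling error;
- Tinetti balance/gait scores drawn from discrete per-group profiles
  (totals = balance + gait by construction, caps 16/12/28) whose medians,
  quartiles and N-vs-F2+ discrimination reproduce the published clinical
  table; in the default `quantile` sampling mode the profile counts are
  realized exactly;
- trunk ML stLE normal per group (SD 0.12) with the N-to-F2+ mean shift set
  through the closed-form binormal AUC, Φ(Δ/√(σ₁²+σ₂²)) = 0.673, and the F1
  mean at 40% of that shift (the published medians rise monotonically with
  fall count); other sensor/axis exponents carry no group shift, and ltLE
  carries none anywhere (the reference study found none);
- a Gaussian-copula coupling (latent correlation 0.55) between clinical
  deficit and trunk ML stLE. This is the one genuinely free joint
  parameter; it was fixed by matching the expected logistic-combination
  AUCs of the N-vs-F2+ comparison to the published combined-predictor
  block, averaged over seeds, and is not adjusted per seed.

Sampling modes: `quantile` (default) realizes each group's marginals
deterministically (midpoint-quantile grids, exact discrete counts) and uses
the seed only for couplings — the representative cohort for reproduction
work; `random` draws everything iid — the right mode for calibration
studies (type-I error, null AUC distributions), where the quantile mode's
variance suppression would be misleading.

## Statistics

- **Mann–Whitney U**: two-sided; exact enumeration when n₁+n₂ ≤ 20 without
  ties, otherwise the tie-corrected normal approximation with continuity
  correction (scipy backend). Identical samples short-circuit to p = 1 with
  a warning. AUC ≡ U/(n₁n₂) under midrank ties; the test suite enforces the
  identity exactly against the trapezoidal ROC AUC.
- **Normality screen**: Lilliefors-corrected Kolmogorov–Smirnov (parameters
  estimated from the sample; the plain KS null would be anti-conservative).
- **Bonferroni**: α/k within each variable family (k = 3 for the clinical
  scores), reported to the conventional 3 decimals (0.05/3 → 0.017).
- **ROC**: trapezoidal AUC over all empirical thresholds; predictor
  direction auto-oriented so AUC ≥ 0.5 with the orientation recorded
  (higher stLE → faller-positive, lower Tinetti → faller-positive); the
  positive class is the faller group of the comparison. Youden cut-off ties
  resolve to higher specificity.
- **Logistic combination**: unregularized maximum likelihood with
  intercept (statsmodels Newton); collinear columns are dropped via a
  pivoted Gram–Schmidt so duplicated predictors add exactly nothing;
  complete separation is flagged and the ROC computed on the separating
  score. In-sample (apparent) predicted probabilities feed the ROC — no
  cross-validation, matching how combined AUCs are conventionally reported
  in this literature.

## Problem sizes used in the checks

The acceptance checks run the signals chain at 131 subjects × 50 analysed
strides (70 simulated, turns excised) on the trunk sensor — the package's
scaled stride count for routine verification; the per-subject chain is
identical at 150 strides, only slower. Stochastic calibrations use 1,000
null replicates (Mann–Whitney type-I error), 100 null cohorts (AUC and
false-significance rates), 20 seeds × 4 perturbation levels (stLE
monotonicity), and 40 replicate cohorts for the expectation of the
seed-dependent combined AUCs.

## Known limitations

- The heel-strike realization is one standard reading of the
  trunk-acceleration contact rule; other realizations shift contacts by a
  few samples (harmless for LDS, which never uses absolute event times —
  only stride segmentation).
- The resampling maps the concatenated series globally; per-stride
  time-normalization would change exponent values slightly. Whether the
  reference processing resampled per sensor-axis jointly or independently
  is not documented; here all axes of a sensor share the stride grid.
- AMI on noise-free perfectly periodic signals is ill-posed for the
  histogram estimator (1-D joint support); the windowed minimum and the
  fixed cohort delays are the practical defenses.
- Synthetic-cohort AUC reproduction validates the statistics pipeline, not
  the clinical claim; only the deposited per-subject data could do the
  latter, and the cohort-table entry mode accepts exactly such a table.
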