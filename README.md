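# gaitlds

Local dynamic stability of gait from wearable accelerometry, and the
statistics used to judge whether it predicts falls in elderly people.

## The problem

Elderly fallers are hard to identify before they fall. One candidate marker
is *local dynamic stability* (LDS): how fast the walking pattern diverges
after the small, naturally occurring perturbations of every stride. LDS is
quantified by finite-time Lyapunov exponents of the reconstructed gait
attractor — the scalar acceleration series x(t) from a trunk- or
shank-mounted sensor is delay-embedded,

&nbsp;&nbsp;**X**(t) = [x(t), x(t+τ), …, x(t+(d−1)τ)],

each embedded state is paired with its Euclidean-nearest neighbour at least
one stride away in time (Theiler window), and the mean log separation of
those pairs, ⟨ln dⱼ(k)⟩, is tracked forward (Rosenstein's algorithm). Two
slopes of that divergence curve are the outcomes:

- **stLE** — slope over 0–0.5 stride (≈ one step): the immediate response to
  a perturbation; higher = less stable;
- **ltLE** — slope over strides 4–10: slow divergence far from the
  perturbation.

The package implements the full chain for a 131-subject prospective
fall-risk protocol: startup trim (300 samples), U-turn excision with a
one-stride guard, heel-strike stride extraction from the anterior–posterior
trunk acceleration, resampling of 150 strides to 15,000 points
(≈100/stride), embedding with fixed cohort delays (trunk V/ML/AP = 11/8/10
samples, shank = 9/6/11, dimension 6 by false-nearest-neighbours), FFT
stride frequency, and the predictive-validity statistics: Mann–Whitney U
contrasts between non-fallers (N), single fallers (F1) and multiple fallers
(F2+), ROC/AUC per predictor with Youden-J cut-offs
(J = max{specificity + sensitivity − 1}), and unregularized logistic
combinations of clinical (Tinetti) scores with trunk ML stLE.

Because raw signals of the reference cohort are not redistributable, a
first-class synthetic-data module generates (a) quasi-periodic tri-axial
gait signals with a tunable stride-to-stride perturbation magnitude and
annotated turns, and (b) cohort tables calibrated to the reference study's
group structure — so every stage is testable end to end, and an independent
Benettin tangent-space oracle on the Lorenz system validates the Rosenstein
estimator.

## Worked example

```python
from gaitlds import (GaitSimConfig, LdsConfig, default_embedding,
                     detect_heel_strikes, excise_turns, select_and_resample,
                     series_lyapunov, simulate_gait, stride_frequency,
                     trim_startup)

sim = simulate_gait(GaitSimConfig(seed=42, perturbation_sd=0.05))  # 5-min walk
rec = trim_startup(sim.recordings["trunk_L5"], 300)
events = detect_heel_strikes(rec)
segments = excise_turns(rec, events, sim.turns)
series = select_and_resample(rec, segments, n_strides=150, samples_per_stride=100)
spec = default_embedding("trunk_L5", "ml")
result, curve = series_lyapunov(series["ml"].x, spec, LdsConfig())
print(f"strides detected: {events.n_strides}")
print(f"stride frequency: {stride_frequency(rec, segments=segments):.3f} Hz")
print(f"stLE (0-0.5 stride): {result.stle:.3f} per stride")
print(f"ltLE (4-10 strides): {result.ltle:.3f} per stride")
```

prints

```
strides detected: 283
stride frequency: 0.952 Hz
stLE (0-0.5 stride): 1.759 per stride
ltLE (4-10 strides): 0.033 per stride
```

283 strides of the simulated 5-minute corridor walk survive detection; the
stride rhythm is recovered at 0.952 Hz (built at 0.955); the short-term
exponent of 1.76 per stride is in the range typical of trunk ML acceleration
at moderate stride-to-stride variability, while the long-term exponent is an
order of magnitude smaller — divergence has largely saturated by the fourth
stride.

Cohort-level analysis runs from a per-subject metric table:

```bash
gaitlds simulate cohort --seed 0 --out demo/
gaitlds cohort --table demo/cohort.csv --compare N:F2+ \
    --predictors tinetti_balance,tinetti_total,stle_trunk_ml --out demo/report
```

`demo/report/report.json` then carries group medians/quartiles with
Bonferroni-adjusted Mann–Whitney p-values and the single/combined ROC rows
(AUC, Youden cut-off, specificity, sensitivity, logistic coefficients).
A `gaitlds run --config run.yaml` entry point orchestrates either mode;
`simulate`, `preprocess`, `embed` and `lds` subcommands expose the
intermediate stages.

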