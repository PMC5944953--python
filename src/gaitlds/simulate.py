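"""Synthetic gait signals and cohorts with controllable instability.

Two generators back the test surface of the whole pipeline:

``simulate_gait`` builds quasi-periodic tri-axial trunk/shank acceleration as
stride-locked harmonic series with per-stride random phase and amplitude
jitter (the tunable local-instability dial), additive sensor noise, a startup
transient, and amplitude-disrupted U-turn intervals, exporting ground-truth
heel-strike times and turn spans.  The medial-lateral axis oscillates at the
stride frequency, the anterior-posterior and vertical axes at the step
frequency with a stride-locked left/right asymmetry component - the
periodicity structure of real trunk acceleration.

``simulate_cohort`` builds per-subject predictor tables with the three
prospective fall groups (N / F1 / F2+).  Its default parameters are
calibrated to the published elderly fall-risk cohort this package models:
group sizes 81/35/15, demographic moments per group, discrete Tinetti
balance/gait distributions whose medians, quartiles and single-variable
discrimination match the reference tables, and a medial-lateral short-term
Lyapunov effect size set through the closed-form binormal AUC.  In the
default ``quantile`` sampling mode each group's marginal distribution is
realized exactly (moment-matched demographics, count-exact discrete scores,
midpoint-quantile grids for continuous metrics) and the seed drives only the
coupling between variables; ``random`` sampling draws everything iid for
calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import AccelRecording, CohortTable, TurnAnnotation

# ---------------------------------------------------------------------------
# gait-signal generator


@dataclass
class GaitSimConfig:
    """Configuration for the quasi-periodic gait-signal generator.

    ``perturbation_sd`` is the per-stride jitter scale, as a fraction of the
    cycle: stride durations are scaled by ``1 + N(0, sd)`` and per-stride
    amplitudes by the same law.  Defaults mirror a 5-minute corridor walk at
    296.3 Hz with a stride frequency of 0.955 Hz and a U-turn roughly every
    25 m (19 strides).
    """

    n_strides: int = 285
    fs: float = 296.3
    stride_freq: float = 0.955
    perturbation_sd: float = 0.05
    sensor_noise_sd: float = 0.03
    startup_samples: int = 300
    turn_every: int | None = 19
    turn_duration: int = 2
    asymmetry: float = 0.18
    amplitudes: dict = field(default_factory=lambda: {
        # harmonic amplitudes (m s^-2); AP/V at step frequency, ML at stride
        "ap": (1.2, 0.45, 0.20),
        "v": (1.6, 0.50, 0.20),
        "ml": (0.55, 0.30, 0.22, 0.15, 0.10),
    })
    shank_gain: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 20.0 * self.stride_freq:
            raise ValueError(
                f"fs={self.fs} too low to resolve 10 harmonics of {self.stride_freq} Hz"
            )
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be >= 0")
        if self.n_strides < 3:
            raise ValueError("need at least 3 strides")

    @property
    def turn_spec(self) -> list[tuple[int, int]]:
        """Turn placements as (start stride, duration in strides)."""
        if self.turn_every is None:
            return []
        return [
            (s, self.turn_duration)
            for s in range(self.turn_every, self.n_strides - self.turn_duration - 2,
                           self.turn_every + self.turn_duration)
        ]


@dataclass
class GaitSimResult:
    recordings: dict[str, AccelRecording]
    heel_strike_times: np.ndarray  # same-side contacts (stride starts), s
    step_times: np.ndarray  # both-side contacts, s
    turn_intervals: list[tuple[float, float]]
    config: GaitSimConfig

    @property
    def turns(self) -> TurnAnnotation | None:
        if not self.turn_intervals:
            return None
        return TurnAnnotation(intervals=self.turn_intervals)


def simulate_gait(config: GaitSimConfig) -> GaitSimResult:
    """Generate tri-axial recordings for trunk and both shanks."""
    rng = np.random.default_rng(config.seed)
    ns = config.n_strides
    base_T = 1.0 / config.stride_freq

    in_turn = np.zeros(ns, dtype=bool)
    for start, dur in config.turn_spec:
        in_turn[start : start + dur] = True

    dur_jit = rng.normal(0.0, config.perturbation_sd, ns)
    amp_jit = rng.normal(0.0, config.perturbation_sd, ns)
    T = base_T * np.clip(1.0 + dur_jit, 0.5, 1.5)
    T[in_turn] *= 1.4  # turning strides are slower
    amp = np.clip(1.0 + amp_jit, 0.2, 1.8)
    amp[in_turn] *= 0.45  # oscillation disrupted during the U-turn

    bounds = np.concatenate([[0.0], np.cumsum(T)])  # stride start times
    total = bounds[-1]
    n = int(np.floor(total * config.fs))
    t = np.arange(n) / config.fs
    # piecewise-linear stride phase (cycles), then per-sample stride index
    phase = np.interp(t, bounds, np.arange(ns + 1))
    stride_idx = np.minimum(phase.astype(int), ns - 1)
    env = amp[stride_idx]
    theta = 2.0 * np.pi * phase  # stride phase, rad
    psi = 2.0 * theta  # step phase, rad

    # step-phase offsets make left/right contacts distinguishable; the
    # asymmetry component at stride frequency is what the stride-frequency
    # spectrum picks up on the AP axis
    def trunk_axis(axis: str) -> np.ndarray:
        a = config.amplitudes[axis]
        if axis == "ml":
            sig = sum(ai * np.sin((h + 1) * theta + 0.8 * h) for h, ai in enumerate(a))
        else:
            sig = sum(ai * np.cos((h + 1) * psi + (0.6 * h if axis == "v" else 0.0))
                      for h, ai in enumerate(a))
            sig += config.asymmetry * a[0] * np.cos(theta)
        return env * sig

    turn_intervals = [(float(bounds[s]), float(bounds[s + d])) for s, d in config.turn_spec]
    # extra low-frequency sway during turns
    sway = np.zeros(n)
    for a_s, b_s in turn_intervals:
        m = (t >= a_s) & (t < b_s)
        sway[m] += 0.4 * np.sin(2.0 * np.pi * 0.25 * (t[m] - a_s))

    startup = 2.5 * np.exp(-np.arange(n) / (0.25 * config.fs))

    recordings: dict[str, AccelRecording] = {}
    for sensor, gain, phase_off in (
        ("trunk_L5", 1.0, 0.0),
        ("shank_left", config.shank_gain, 0.0),
        ("shank_right", config.shank_gain, np.pi),
    ):
        axes = {}
        for axis in ("ap", "v", "ml"):
            sig = trunk_axis(axis) * gain
            if phase_off and axis != "ml":
                # opposite-side shank: impact pattern shifted by one step
                a = config.amplitudes[axis]
                sig = env * gain * sum(
                    ai * np.cos((h + 1) * (psi + phase_off) + (0.6 * h if axis == "v" else 0.0))
                    for h, ai in enumerate(a)
                )
                sig += gain * config.asymmetry * a[0] * np.cos(theta + phase_off / 2.0)
            sig = sig + startup + rng.normal(0.0, config.sensor_noise_sd, n)
            if axis == "ml":
                sig = sig + sway * gain
            axes[axis] = sig
        recordings[sensor] = AccelRecording(
            sensor_id=sensor, fs=config.fs, t=t,
            a_ap=axes["ap"], a_v=axes["v"], a_ml=axes["ml"],
        )

    step_times = np.sort(np.concatenate([bounds[:-1], bounds[:-1] + T / 2.0]))
    return GaitSimResult(
        recordings=recordings,
        heel_strike_times=bounds[:-1],
        step_times=step_times,
        turn_intervals=turn_intervals,
        config=config,
    )


# ---------------------------------------------------------------------------
# cohort generator

#: (balance, gait, count) rows per group, calibrated so Tinetti medians,
#: quartiles and N-vs-F2+ discrimination match the reference cohort; totals
#: are balance + gait by construction (max 16 + 12 = 28).
TINETTI_PROFILE_STUDY = {
    "N": ((16, 12, 60), (15, 12, 8), (16, 11, 5), (16, 10, 5), (14, 11, 3)),
    "F1": ((16, 12, 20), (15, 12, 3), (16, 11, 7), (16, 10, 3), (14, 11, 2)),
    "F2+": ((16, 12, 4), (16, 11, 5), (14, 12, 3), (15, 11, 1), (13, 12, 1), (12, 12, 1)),
}

#: demographic (mean, sd) per group: age (y), height (cm), weight (kg)
DEMOGRAPHICS_STUDY = {
    "N": {"age": (70.5, 6.4), "height": (163.6, 7.8), "weight": (77.5, 14.8)},
    "F1": {"age": (71.4, 7.7), "height": (160.3, 7.1), "weight": (71.6, 11.4)},
    "F2+": {"age": (71.2, 5.3), "height": (161.5, 6.4), "weight": (72.5, 9.3)},
}

#: gait metrics (median ~ mean, sd from IQR/1.349) per group
GAIT_METRICS_STUDY = {
    "N": {"gait_speed": (1.24, 0.156), "stride_frequency": (0.955, 0.0526)},
    "F1": {"gait_speed": (1.25, 0.171), "stride_frequency": (0.949, 0.0808)},
    "F2+": {"gait_speed": (1.20, 0.148), "stride_frequency": (0.989, 0.0815)},
}

#: females / males per group
SEX_STUDY = {"N": (63, 18), "F1": (31, 4), "F2+": (14, 1)}

#: baseline fall-history means (falls in the 3 months before baseline)
BASELINE_FALLS_STUDY = {"N": 0.10, "F1": 0.20, "F2+": 0.13}

_STLE_SENSORS = ("trunk", "shank_left", "shank_right")
_AXES = ("ap", "v", "ml")
#: non-discriminative stability baselines (per-stride rates)
_STLE_BASE = {"trunk": {"ap": 2.00, "v": 1.90, "ml": 1.30},
              "shank_left": {"ap": 2.45, "v": 2.35, "ml": 1.75},
              "shank_right": {"ap": 2.45, "v": 2.35, "ml": 1.75}}
_LTLE_BASE = 0.10


def binormal_auc(delta: float, sd0: float, sd1: float) -> float:
    """Closed-form AUC of two normals: Phi(delta / sqrt(sd0^2 + sd1^2))."""
    return float(norm.cdf(delta / np.hypot(sd0, sd1)))


def delta_for_auc(auc: float, sd0: float, sd1: float) -> float:
    """Mean shift giving a target binormal AUC (inverse of binormal_auc)."""
    return float(norm.ppf(auc) * np.hypot(sd0, sd1))


@dataclass
class CohortSimConfig:
    """Configuration for the synthetic fall-risk cohort.

    ``stle_ml_target_auc`` fixes the N-vs-F2+ mean shift of the trunk
    medial-lateral short-term exponent through the closed-form binormal AUC;
    ``stle_tinetti_corr`` is the latent (Gaussian-copula) correlation between
    clinical deficit and trunk ML instability.  ``tinetti_profile`` /
    demographic tables default to the reference-cohort calibration and can be
    set to ``"null"`` for no group differences at all.
    """

    n_per_group: tuple[int, int, int] = (81, 35, 15)
    stle_ml_mean_n: float = 1.30
    stle_ml_sd: float = 0.12
    stle_ml_target_auc: float = 0.673
    stle_ml_f1_frac: float = 0.4  # F1 shift as a fraction of the F2+ shift
    tinetti_profile: str = "study"  # "study" | "null"
    demographics_profile: str = "study"
    stle_tinetti_corr: float = 0.55
    sampling: str = "quantile"  # "quantile" (representative) | "random" (iid)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("every group needs at least 1 subject")
        if not 0 <= abs(self.stle_tinetti_corr) < 1:
            raise ValueError("stle_tinetti_corr must be in (-1, 1)")
        if self.sampling not in ("quantile", "random"):
            raise ValueError(f"unknown sampling mode '{self.sampling}'")


def _counts_from_rows(rows, n: int) -> list[tuple[int, int, int]]:
    """Rescale a (balance, gait, count) profile to n subjects (largest remainder)."""
    total = sum(r[2] for r in rows)
    raw = [r[2] * n / total for r in rows]
    counts = [int(np.floor(v)) for v in raw]
    rem = n - sum(counts)
    order = np.argsort([c - v for c, v in zip(counts, raw)])  # largest remainder first
    for i in order[:rem]:
        counts[i] += 1
    return [(b, g, c) for (b, g, _), c in zip(rows, counts)]


def _quantile_grid(n: int, mu: float, sd: float) -> np.ndarray:
    """Midpoint-quantile realization of N(mu, sd); mean is exactly mu."""
    return mu + sd * norm.ppf((np.arange(n) + 0.5) / n)


def _moment_matched(rng, n: int, mu: float, sd: float) -> np.ndarray:
    z = rng.normal(size=n)
    if n > 1 and np.std(z) > 0:
        z = (z - z.mean()) / z.std()
    else:
        z = np.zeros(n)
    return mu + sd * z


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortTable, dict]:
    """Generate a per-subject cohort table plus its ground-truth effect sizes."""
    rng = np.random.default_rng(config.seed)
    groups = ("N", "F1", "F2+")
    ns = dict(zip(groups, config.n_per_group))
    null_tinetti = config.tinetti_profile == "null"
    null_demo = config.demographics_profile == "null"

    delta = delta_for_auc(config.stle_ml_target_auc, config.stle_ml_sd, config.stle_ml_sd)
    stle_ml_means = {
        "N": config.stle_ml_mean_n,
        "F1": config.stle_ml_mean_n + config.stle_ml_f1_frac * delta,
        "F2+": config.stle_ml_mean_n + delta,
    }
    if null_tinetti:  # null cohorts carry no stability shift either
        stle_ml_means = {g: config.stle_ml_mean_n for g in groups}

    records = []
    sid = 0
    for g in groups:
        n = ns[g]
        profile_key = "N" if null_tinetti else g
        demo_key = "N" if null_demo else g
        rows = _counts_from_rows(TINETTI_PROFILE_STUDY[profile_key], n)
        if config.sampling == "quantile":
            bal = np.concatenate([[b] * c for b, _, c in rows])
            gai = np.concatenate([[gg] * c for _, gg, c in rows])
        else:
            p = np.array([c for *_, c in rows], dtype=float)
            pick = rng.choice(len(rows), size=n, p=p / p.sum())
            bal = np.array([rows[i][0] for i in pick])
            gai = np.array([rows[i][1] for i in pick])
        tot = bal + gai

        # latent clinical-deficit score drives the stLE coupling; random
        # tie-jitter orders equal scores, the copula noise is seeded
        z_def = -(tot - np.mean(tot))
        z_def = z_def / (np.std(z_def) if np.std(z_def) > 0 else 1.0)
        rho = config.stle_tinetti_corr
        z = rho * z_def + np.sqrt(1.0 - rho**2) * rng.normal(size=n)

        if config.sampling == "quantile":
            stle_ml_sorted = np.sort(
                _quantile_grid(n, stle_ml_means[g], config.stle_ml_sd))
            stle_ml = np.empty(n)
            stle_ml[np.argsort(z, kind="stable")] = stle_ml_sorted
        else:
            stle_ml = stle_ml_means[g] + config.stle_ml_sd * (
                rho * z_def + np.sqrt(1.0 - rho**2) * rng.normal(size=n))

        demo = DEMOGRAPHICS_STUDY[demo_key]
        gaitm = GAIT_METRICS_STUDY["N" if null_demo else g]
        draw = _moment_matched if config.sampling == "quantile" else (
            lambda r, n_, mu, sd: mu + sd * r.normal(size=n_))
        age = draw(rng, n, *demo["age"])
        height = draw(rng, n, *demo["height"])
        weight = draw(rng, n, *demo["weight"])
        bmi = weight / (height / 100.0) ** 2

        def metric(mu_sd):
            if config.sampling == "quantile":
                vals = _quantile_grid(n, *mu_sd)
                return rng.permutation(vals)
            return mu_sd[0] + mu_sd[1] * rng.normal(size=n)

        speed = metric(gaitm["gait_speed"])
        sfreq = metric(gaitm["stride_frequency"])

        n_f, n_m = SEX_STUDY[demo_key]
        n_f = min(n, int(round(n * n_f / (n_f + n_m))))
        sex = rng.permutation(np.array(["F"] * n_f + ["M"] * (n - n_f)))

        mean_bf = BASELINE_FALLS_STUDY[demo_key]
        n_bf = int(round(mean_bf * n))
        bfalls = np.zeros(n, dtype=int)
        bfalls[: min(n_bf, n)] = 1
        bfalls = rng.permutation(bfalls)

        if g == "N":
            pfalls = np.zeros(n, dtype=int)
        elif g == "F1":
            pfalls = np.ones(n, dtype=int)
        else:
            pfalls = rng.permutation(np.array([2] * (n - n // 5) + [3] * (n // 5)))

        other = {}
        for sensor in _STLE_SENSORS:
            for axis in _AXES:
                key = f"{sensor}_{axis}"
                if sensor == "trunk" and axis == "ml":
                    other[f"stle_{key}"] = stle_ml
                else:
                    mu = _STLE_BASE[sensor][axis]
                    other[f"stle_{key}"] = metric((mu, 0.15))
                other[f"ltle_{key}"] = metric((_LTLE_BASE, 0.03))

        for i in range(n):
            sid += 1
            rec = {
                "subject_id": f"S{sid:03d}",
                "sex": sex[i],
                "age": age[i],
                "height": height[i],
                "weight": weight[i],
                "bmi": bmi[i],
                "baseline_falls": int(bfalls[i]),
                "tinetti_balance": int(bal[i]),
                "tinetti_gait": int(gai[i]),
                "tinetti_total": int(tot[i]),
                "gait_speed": speed[i],
                "stride_frequency": sfreq[i],
                "prospective_falls": int(pfalls[i]),
            }
            for key, vals in other.items():
                rec[key] = float(vals[i])
            records.append(rec)

    import pandas as pd

    table = CohortTable(pd.DataFrame.from_records(records))
    truth = {
        "stle_ml_means": stle_ml_means,
        "stle_ml_sd": config.stle_ml_sd,
        "stle_ml_true_auc": binormal_auc(
            stle_ml_means["F2+"] - stle_ml_means["N"],
            config.stle_ml_sd, config.stle_ml_sd),
        "tinetti_profile": config.tinetti_profile,
        "stle_tinetti_corr": config.stle_tinetti_corr,
    }
    return table, truth
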