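"""Rosenstein nearest-neighbour divergence and Lyapunov slope fits.

For every embedded state the Euclidean-nearest neighbour outside a temporal
exclusion (Theiler) window of one mean period (one stride) is tracked forward;
the mean natural-log separation versus time, averaged over the pairs still in
range at each horizon (shrinking mean), is the divergence curve.  The
short-term exponent is the least-squares slope over 0-0.5 stride (one step),
the long-term exponent the slope over strides 4-10; units are ln-divergence
per stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import AXES, AccelRecording, TurnAnnotation
from .preprocess import (
    GaitProcessingError,
    detect_heel_strikes,
    excise_turns,
    select_and_resample,
    stride_frequency,
    trim_startup,
)
from .state_space import EmbeddingSpec, StateTrajectory, computed_embedding, default_embedding, delay_embed

#: floor applied to neighbour distances before the log (guards exact clones)
DISTANCE_FLOOR = 1e-12


class LyapunovError(ValueError):
    pass


@dataclass
class DivergenceCurve:
    """Mean log Euclidean separation of neighbour pairs vs time in strides."""

    t_strides: np.ndarray
    mean_log_div: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.t_strides = np.asarray(self.t_strides, dtype=float)
        self.mean_log_div = np.asarray(self.mean_log_div, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class LyapunovResult:
    stle: float
    ltle: float
    fit_r2: dict = field(default_factory=dict)
    spec: EmbeddingSpec | None = None


def nearest_neighbor_pairs(traj: StateTrajectory, theiler: int | None = None) -> np.ndarray:
    """For each reference point, its Euclidean-nearest temporally-separated point.

    ``theiler`` is the temporal exclusion half-window in samples; neighbours
    with ``|i - j| <= theiler`` are inadmissible (default: one stride, the
    mean-period rule).  Returns an (n, 2) array of (reference, neighbour)
    index pairs.
    """
    X = traj.points
    n = X.shape[0]
    if theiler is None:
        theiler = traj.samples_per_stride
    theiler = int(theiler)
    idx_all = np.arange(n)
    # admissible-neighbour counts are known in closed form from the window
    window = np.minimum(idx_all + theiler, n - 1) - np.maximum(idx_all - theiler, 0) + 1
    admissible_counts = n - window
    if np.mean(admissible_counts == 0) > 0.10:
        raise LyapunovError(
            f"trajectory too short for exclusion window ({theiler} samples, {n} points)"
        )
    tree = cKDTree(X)
    neighbor = np.full(n, -1, dtype=int)
    k = min(n, 32)
    while True:
        dist, idx = tree.query(X, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        ok = np.abs(idx - idx_all[:, None]) > theiler
        has = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        neighbor[has] = idx[np.arange(n), first][has]
        unresolved = ~has & (admissible_counts > 0)
        if not unresolved.any() or k >= n:
            break
        k = min(n, max(2 * k, 2 * theiler + 2))
    refs = idx_all[neighbor >= 0]
    return np.column_stack([refs, neighbor[refs]])


def divergence_curve(
    traj: StateTrajectory,
    pairs: np.ndarray,
    horizon_strides: float = 10.0,
    min_pairs_frac: float = 0.05,
) -> DivergenceCurve:
    """Mean log divergence of neighbour pairs over ``horizon_strides``.

    At horizon step k only pairs with both trajectories still in range are
    averaged (shrinking mean); distances are floored at ``DISTANCE_FLOOR``
    before the natural log.
    """
    if pairs.size == 0:
        raise LyapunovError("empty neighbour-pair set")
    X = traj.points
    n = X.shape[0]
    sps_ = traj.samples_per_stride
    K = int(round(horizon_strides * sps_))
    m = np.maximum(pairs[:, 0], pairs[:, 1])
    order = np.argsort(m)
    i_s = pairs[order, 0]
    j_s = pairs[order, 1]
    m_s = m[order]
    n_alive_end = int(np.searchsorted(m_s, n - 1 - K, side="right"))
    if n_alive_end < max(1, min_pairs_frac * len(pairs)):
        raise LyapunovError(
            f"horizon of {horizon_strides} strides leaves only {n_alive_end} of "
            f"{len(pairs)} pairs in range (< {min_pairs_frac:.0%})"
        )
    mean_log = np.empty(K + 1)
    n_pairs = np.empty(K + 1, dtype=int)
    for k in range(K + 1):
        alive = int(np.searchsorted(m_s, n - 1 - k, side="right"))
        n_pairs[k] = alive
        if alive == 0:
            mean_log[k] = np.nan
            continue
        d = X[i_s[:alive] + k] - X[j_s[:alive] + k]
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        np.maximum(dist, DISTANCE_FLOOR, out=dist)
        mean_log[k] = float(np.mean(np.log(dist)))
    t = np.arange(K + 1) / sps_
    return DivergenceCurve(t_strides=t, mean_log_div=mean_log, n_pairs=n_pairs)


def _window_slope(curve: DivergenceCurve, lo: float, hi: float) -> tuple[float, float]:
    eps = 1e-9
    mask = (curve.t_strides >= lo - eps) & (curve.t_strides <= hi + eps)
    mask &= np.isfinite(curve.mean_log_div) & (curve.n_pairs > 0)
    if mask.sum() < 3:
        raise LyapunovError(f"fit window [{lo}, {hi}] strides has < 3 usable points")
    t = curve.t_strides[mask]
    y = curve.mean_log_div[mask]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def fit_lyapunov(
    curve: DivergenceCurve,
    st_window: tuple[float, float] = (0.0, 0.5),
    lt_window: tuple[float, float] = (4.0, 10.0),
    spec: EmbeddingSpec | None = None,
) -> LyapunovResult:
    """Short- and long-term exponents as slopes over the two fit windows.

    Windows are inclusive of both endpoints on the sample grid; units are
    ln-divergence per stride.
    """
    stle, r2_st = _window_slope(curve, *st_window)
    ltle, r2_lt = _window_slope(curve, *lt_window)
    return LyapunovResult(stle=stle, ltle=ltle,
                          fit_r2={"st": r2_st, "lt": r2_lt}, spec=spec)


@dataclass
class LdsConfig:
    """End-to-end stride-series / stability configuration."""

    startup_samples: int = 300
    n_strides: int = 150
    samples_per_stride: int = 100
    horizon_strides: float = 10.0
    st_window: tuple[float, float] = (0.0, 0.5)
    lt_window: tuple[float, float] = (4.0, 10.0)
    theiler_strides: float = 1.0
    embedding: str = "fixed"  # "fixed" cohort defaults | "computed" per series
    resample_method: str = "cubic"
    selection: str = "first"


def series_lyapunov(
    x: np.ndarray,
    spec: EmbeddingSpec,
    config: LdsConfig = LdsConfig(),
) -> tuple[LyapunovResult, DivergenceCurve]:
    """Rosenstein analysis of one resampled stride series."""
    traj = delay_embed(x, spec, samples_per_stride=config.samples_per_stride)
    theiler = int(round(config.theiler_strides * config.samples_per_stride))
    pairs = nearest_neighbor_pairs(traj, theiler=theiler)
    curve = divergence_curve(traj, pairs, horizon_strides=config.horizon_strides)
    result = fit_lyapunov(curve, config.st_window, config.lt_window, spec=spec)
    return result, curve


def lds_pipeline(
    recordings: dict[str, AccelRecording],
    config: LdsConfig = LdsConfig(),
    turns: TurnAnnotation | None = None,
) -> dict:
    """Full per-subject analysis: trim, events, excision, resample, exponents.

    Heel strikes are detected on the trunk AP channel and applied to every
    synchronized sensor.  Returns ``{"lyapunov": {(sensor, axis): result},
    "stride_frequency": Hz, "events": GaitEvents}``; deterministic for fixed
    inputs and configuration.
    """
    trunk_key = next((k for k in recordings if k.startswith("trunk")), None)
    if trunk_key is None:
        raise LyapunovError("a trunk recording is required for heel-strike detection")
    trimmed = {}
    for key, rec in recordings.items():
        try:
            trimmed[key] = trim_startup(rec, config.startup_samples)
        except GaitProcessingError as exc:
            raise LyapunovError(f"[trim:{key}] {exc}") from exc
    try:
        events = detect_heel_strikes(trimmed[trunk_key])
    except GaitProcessingError as exc:
        raise LyapunovError(f"[events:{trunk_key}] {exc}") from exc
    try:
        trunk_segments = excise_turns(trimmed[trunk_key], events, turns)
        freq = stride_frequency(trimmed[trunk_key], segments=trunk_segments)
    except GaitProcessingError:
        freq = float("nan")
    results: dict[tuple[str, str], LyapunovResult] = {}
    for key, rec in trimmed.items():
        try:
            segments = excise_turns(rec, events, turns)
            series = select_and_resample(
                rec, segments, config.n_strides, config.samples_per_stride,
                selection=config.selection, method=config.resample_method,
            )
        except GaitProcessingError as exc:
            raise LyapunovError(f"[strides:{key}] {exc}") from exc
        for axis in AXES:
            x = series[axis].x
            if config.embedding == "fixed":
                spec = default_embedding(rec.sensor_id, axis)
            else:
                spec = computed_embedding(x, samples_per_stride=config.samples_per_stride)
            try:
                result, _ = series_lyapunov(x, spec, config)
            except (LyapunovError, ValueError) as exc:
                raise LyapunovError(f"[lyapunov:{key}/{axis}] {exc}") from exc
            results[(key, axis)] = result
    return {"lyapunov": results, "stride_frequency": freq, "events": events}
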