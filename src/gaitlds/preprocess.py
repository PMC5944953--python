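"""Turn raw recordings into analysis-ready stride series.

Stages: startup trim (sensor settling), heel-strike detection from the
anterior-posterior trunk acceleration (peak preceding the positive-to-negative
zero crossing of the low-pass-filtered signal, a standard realization of the
trunk-accelerometry contact rule), U-turn excision with a one-stride guard on
each side, selection of a fixed stride count resampled to a uniform grid of
~100 samples per stride, and FFT stride frequency.  Analyses downstream run on
the unfiltered signal; filtering is used only inside event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import AXES, AccelRecording, TurnAnnotation

PHYSIOLOGIC_STRIDE_S = (0.6, 2.5)


class GaitProcessingError(ValueError):
    """Raised when a recording cannot be turned into valid stride series."""


@dataclass
class GaitEvents:
    """Heel-strike (same-side foot contact) events on the trunk AP signal."""

    heel_strike_idx: np.ndarray  # stride-level contacts, sample indices
    fs: float
    step_idx: np.ndarray | None = None  # both-side contacts, if available

    def __post_init__(self) -> None:
        self.heel_strike_idx = np.asarray(self.heel_strike_idx, dtype=int)
        if np.any(np.diff(self.heel_strike_idx) <= 0):
            raise GaitProcessingError("heel-strike indices must be strictly increasing")
        med = np.median(self.stride_durations) if self.n_strides else np.nan
        if self.n_strides and not (PHYSIOLOGIC_STRIDE_S[0] <= med <= PHYSIOLOGIC_STRIDE_S[1]):
            warnings.warn(
                f"median stride duration {med:.2f} s outside physiologic "
                f"range {PHYSIOLOGIC_STRIDE_S}", stacklevel=2,
            )

    @property
    def stride_durations(self) -> np.ndarray:
        return np.diff(self.heel_strike_idx) / self.fs

    @property
    def n_strides(self) -> int:
        return max(0, self.heel_strike_idx.size - 1)


@dataclass
class WalkSegment:
    """A contiguous straight-walking span, bounded by heel strikes.

    ``stride_bounds`` holds ``n+1`` sample indices delimiting ``n`` strides.
    """

    stride_bounds: np.ndarray

    def __post_init__(self) -> None:
        self.stride_bounds = np.asarray(self.stride_bounds, dtype=int)

    @property
    def n_strides(self) -> int:
        return max(0, self.stride_bounds.size - 1)


@dataclass
class StrideSeries:
    """A fixed-stride-count signal resampled to a uniform per-stride grid."""

    x: np.ndarray
    n_strides: int
    samples_per_stride: int
    source_axis: str
    source_sensor: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size != self.n_strides * self.samples_per_stride:
            raise GaitProcessingError(
                f"stride series length {self.x.size} != "
                f"{self.n_strides} x {self.samples_per_stride}"
            )


def trim_startup(rec: AccelRecording, n_samples: int = 300) -> AccelRecording:
    """Drop the first ``n_samples`` (sensor settling) from all channels."""
    if n_samples < 0:
        raise GaitProcessingError(f"n_samples must be >= 0, got {n_samples}")
    if n_samples == 0:
        return rec
    if rec.n_samples - n_samples < 2:
        raise GaitProcessingError(
            f"cannot trim {n_samples} samples from a {rec.n_samples}-sample recording"
        )
    return AccelRecording(
        sensor_id=rec.sensor_id,
        fs=rec.fs,
        t=rec.t[n_samples:],
        a_ap=rec.a_ap[n_samples:],
        a_v=rec.a_v[n_samples:],
        a_ml=rec.a_ml[n_samples:],
    )


def _dominant_frequency(x: np.ndarray, fs: float, band: tuple[float, float],
                        resolution: float = 0.01, dominance: float | None = None) -> float:
    """Peak of the zero-padded amplitude spectrum within ``band`` (Hz)."""
    x = np.asarray(x, float) - np.mean(x)
    nfft = int(2 ** np.ceil(np.log2(max(x.size, fs / resolution))))
    amp = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise GaitProcessingError(f"band {band} outside spectral support")
    amp_band = amp[mask]
    peak = int(np.argmax(amp_band))
    if dominance is not None:
        floor = np.median(amp_band)
        if floor <= 0 or amp_band[peak] < dominance * floor:
            raise GaitProcessingError(
                f"no dominant peak in {band} Hz band "
                f"(peak/median = {amp_band[peak] / max(floor, 1e-300):.2f})"
            )
    return float(freqs[mask][peak])


def detect_heel_strikes(
    rec: AccelRecording,
    lowpass_hz: float = 20.0,
    threshold_frac: float = 0.3,
    step_band: tuple[float, float] = (1.0, 3.4),
) -> GaitEvents:
    """Detect heel strikes from the AP trunk acceleration.

    The AP signal is low-pass filtered (zero-phase Butterworth at
    ``lowpass_hz``); positive peaks exceeding an adaptive threshold
    (``threshold_frac`` of the rolling peak amplitude) that precede a
    positive-to-negative zero crossing mark foot contacts.  Both feet produce
    contacts (steps); every second contact is a same-side heel strike, i.e.
    one stride.
    """
    x = rec.a_ap - np.mean(rec.a_ap)
    if np.std(x) < 1e-12:
        raise GaitProcessingError("insufficient gait: constant AP signal")
    nyq = rec.fs / 2.0
    if lowpass_hz < nyq:
        b, a = sps.butter(4, lowpass_hz / nyq, btype="low")
        xf = sps.filtfilt(b, a, x)
    else:
        xf = x
    try:
        f_step = _dominant_frequency(xf, rec.fs, step_band, dominance=4.0)
    except GaitProcessingError as exc:
        raise GaitProcessingError(f"insufficient gait: {exc}") from exc
    min_dist = max(1, int(0.6 * rec.fs / f_step))
    # adaptive threshold: fraction of the rolling peak amplitude (~3 steps)
    win = max(3, int(3.0 * rec.fs / f_step))
    rolling_peak = np.maximum.accumulate(np.abs(xf))  # fallback for short signals
    if xf.size > win:
        from scipy.ndimage import maximum_filter1d
        rolling_peak = maximum_filter1d(np.abs(xf), size=win, mode="nearest")
    peaks, _ = sps.find_peaks(xf, distance=min_dist, height=threshold_frac * rolling_peak)
    if peaks.size < 3:
        raise GaitProcessingError("insufficient gait: fewer than 3 contacts detected")
    # keep only peaks followed by a positive-to-negative zero crossing before
    # the next retained peak (contact is the peak preceding the crossing)
    crossings = np.nonzero((xf[:-1] > 0) & (xf[1:] <= 0))[0]
    if crossings.size == 0:
        raise GaitProcessingError("insufficient gait: no zero crossings")
    # the contact is the last above-threshold peak preceding each crossing
    first_crossing_after = np.searchsorted(crossings, peaks)
    last_peak_for_crossing: dict[int, int] = {}
    for p, ci in zip(peaks, first_crossing_after):
        if ci < crossings.size:
            last_peak_for_crossing[int(ci)] = int(p)  # peaks ascend -> keeps last
    steps = np.asarray(sorted(last_peak_for_crossing.values()), dtype=int)
    strides = steps[0::2]
    if strides.size < 4:  # fewer than 3 strides
        raise GaitProcessingError("insufficient gait: fewer than 3 strides detected")
    return GaitEvents(heel_strike_idx=strides, fs=rec.fs, step_idx=steps)


def excise_turns(
    rec: AccelRecording,
    events: GaitEvents,
    turns: TurnAnnotation | None,
) -> list[WalkSegment]:
    """Split the recording into straight-walk segments.

    For every turn interval the overlapping strides plus one full stride
    before and one after are removed; segment boundaries snap to heel strikes.
    With no turns the full stride set is returned as one segment.
    """
    hs = events.heel_strike_idx
    n_strides = events.n_strides
    if n_strides < 1:
        raise GaitProcessingError("no strides to segment")
    bad = np.zeros(n_strides, dtype=bool)
    if turns is not None:
        t0 = rec.t[0]
        for start_s, end_s in turns.intervals:
            s0 = (start_s - t0) * rec.fs
            s1 = (end_s - t0) * rec.fs
            for k in range(n_strides):
                if hs[k] < s1 and hs[k + 1] > s0:  # stride overlaps turn
                    bad[k] = True
        # guard strides: one before and one after each bad run
        grown = bad.copy()
        grown[:-1] |= bad[1:]
        grown[1:] |= bad[:-1]
        bad = grown
    segments: list[WalkSegment] = []
    k = 0
    while k < n_strides:
        if bad[k]:
            k += 1
            continue
        j = k
        while j < n_strides and not bad[j]:
            j += 1
        segments.append(WalkSegment(stride_bounds=hs[k : j + 1]))
        k = j
    if not segments:
        raise GaitProcessingError("no straight-walk strides remain after turn excision")
    return segments


def select_and_resample(
    rec: AccelRecording,
    segments: list[WalkSegment],
    n_strides: int = 150,
    samples_per_stride: int = 100,
    selection: str = "first",
    method: str = "cubic",
) -> dict[str, StrideSeries]:
    """Concatenate ``n_strides`` straight-walk strides and resample.

    The selected strides (time order; ``selection`` = ``first`` or
    ``middle``) are concatenated and the whole series mapped onto a uniform
    grid of ``n_strides * samples_per_stride`` points (cubic spline by
    default, ``method='linear'`` available), giving ~``samples_per_stride``
    points per stride.  Returns one :class:`StrideSeries` per axis.
    """
    stride_spans = [
        (seg.stride_bounds[i], seg.stride_bounds[i + 1])
        for seg in segments
        for i in range(seg.n_strides)
    ]
    available = len(stride_spans)
    if available < n_strides:
        raise GaitProcessingError(f"insufficient strides ({available} < {n_strides})")
    if selection == "first":
        chosen = stride_spans[:n_strides]
    elif selection == "middle":
        off = (available - n_strides) // 2
        chosen = stride_spans[off : off + n_strides]
    else:
        raise GaitProcessingError(f"unknown selection '{selection}'")
    out: dict[str, StrideSeries] = {}
    n_out = n_strides * samples_per_stride
    for axis in AXES:
        sig = rec.axis(axis)
        xcat = np.concatenate([sig[a:b] for a, b in chosen])
        idx = np.arange(xcat.size)
        grid = np.linspace(0.0, xcat.size - 1.0, n_out)
        if method == "cubic":
            y = CubicSpline(idx, xcat)(grid)
        elif method == "linear":
            y = np.interp(grid, idx, xcat)
        else:
            raise GaitProcessingError(f"unknown resampling method '{method}'")
        out[axis] = StrideSeries(
            x=y,
            n_strides=n_strides,
            samples_per_stride=samples_per_stride,
            source_axis=axis,
            source_sensor=rec.sensor_id,
        )
    return out


def stride_frequency(
    rec: AccelRecording,
    segments: list[WalkSegment] | None = None,
    band: tuple[float, float] = (0.5, 1.5),
    resolution: float = 0.01,
    dominance: float = 5.0,
) -> float:
    """Stride frequency from the zero-padded FFT amplitude spectrum of AP.

    When ``segments`` are given the spectrum is taken on the concatenated
    straight-walk AP samples (turn intervals distort the rhythm), otherwise
    on the whole channel.  The dominant amplitude-spectrum peak within the
    physiologic band is returned; the spectrum is zero-padded so the
    frequency resolution is at most ``resolution`` Hz.  A peak is required to
    exceed ``dominance`` times the in-band median amplitude, otherwise there
    is no discernible gait rhythm and an error is raised.
    """
    if segments is None:
        x = rec.a_ap
    else:
        x = np.concatenate([
            rec.a_ap[seg.stride_bounds[0] : seg.stride_bounds[-1]] for seg in segments
        ])
    if x.size / rec.fs < 30.0:
        raise GaitProcessingError(
            f"need >= 30 s of walking for stride frequency, got {x.size / rec.fs:.1f} s"
        )
    return _dominant_frequency(x, rec.fs, band, resolution, dominance)


def gait_speed(interval_distances_m, interval_times_s) -> float:
    """Mean of per-interval distance/time ratios (m s^-1)."""
    d = np.asarray(interval_distances_m, dtype=float)
    t = np.asarray(interval_times_s, dtype=float)
    if d.size == 0 or d.size != t.size:
        raise GaitProcessingError("distance and time vectors must be equal-length, non-empty")
    if np.any(t <= 0) or np.any(d <= 0):
        raise GaitProcessingError("intervals must have positive distance and time")
    return float(np.mean(d / t))
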