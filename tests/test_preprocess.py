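import numpy as np
import pytest

from gaitlds import (
    AccelRecording,
    GaitSimConfig,
    TurnAnnotation,
    detect_heel_strikes,
    excise_turns,
    gait_speed,
    select_and_resample,
    simulate_gait,
    stride_frequency,
    trim_startup,
)
from gaitlds.preprocess import GaitProcessingError


def _flat_recording(n=1000, fs=296.3):
    t = np.arange(n) / fs
    z = np.zeros(n)
    return AccelRecording("trunk_L5", fs, t, z.copy(), z.copy(), z.copy())


class TestTrimStartup:
    def test_removes_exactly_n(self):
        rec = trim_startup(_flat_recording(1000), 300)
        assert rec.n_samples == 700

    def test_zero_is_identity(self):
        rec = _flat_recording(1000)
        assert trim_startup(rec, 0) is rec

    def test_full_length_trim_fails(self):
        with pytest.raises(GaitProcessingError, match="1000"):
            trim_startup(_flat_recording(1000), 1000)


def _match_rate(detected_t, truth_t, tol):
    recall = np.mean([np.min(np.abs(detected_t - g)) < tol for g in truth_t])
    precision = np.mean([np.min(np.abs(truth_t - d)) < tol for d in detected_t])
    return precision, recall


class TestHeelStrikes:
    def test_counts_one_per_stride(self):
        sim = simulate_gait(GaitSimConfig(seed=2, n_strides=62, stride_freq=1.0,
                                          turn_every=None, perturbation_sd=0.02))
        rec = trim_startup(sim.recordings["trunk_L5"], 300)
        ev = detect_heel_strikes(rec)
        truth = sim.heel_strike_times[sim.heel_strike_times >= rec.t[0]]
        assert abs(ev.heel_strike_idx.size - truth.size) <= 1

    @pytest.mark.parametrize("pert", [0.02, 0.05, 0.1])
    def test_recall_precision_against_ground_truth(self, pert):
        sim = simulate_gait(GaitSimConfig(seed=4, n_strides=80, turn_every=None,
                                          perturbation_sd=pert))
        rec = trim_startup(sim.recordings["trunk_L5"], 300)
        ev = detect_heel_strikes(rec)
        tol = 0.10 / sim.config.stride_freq
        det = rec.t[ev.heel_strike_idx]
        # stride-level truth under either step parity (the detector cannot
        # know which foot the reference side is)
        steps = sim.step_times[sim.step_times >= rec.t[0]]
        best = max(
            _match_rate(det, steps[par::2], tol) for par in (0, 1)
        )
        precision, recall = best
        assert precision >= 0.95
        assert recall >= 0.95

    def test_constant_signal_is_insufficient_gait(self):
        with pytest.raises(GaitProcessingError, match="insufficient gait"):
            detect_heel_strikes(_flat_recording(20000))

    def test_alternating_stride_durations_recovered(self):
        # piecewise-linear stride phase with durations alternating 1.0 / 1.1 s
        fs, durations = 296.3, np.tile([1.0, 1.1], 30)
        bounds = np.concatenate([[0.0], np.cumsum(durations)])
        t = np.arange(int(bounds[-1] * fs)) / fs
        theta = 2 * np.pi * np.interp(t, bounds, np.arange(durations.size + 1))
        ap = 1.2 * np.cos(2 * theta) + 0.45 * np.cos(4 * theta) + 0.18 * np.cos(theta)
        rec = AccelRecording("trunk_L5", fs, t, ap, ap.copy(), ap.copy())
        ev = detect_heel_strikes(rec)
        # build stride durations from both step parities; the correct parity
        # reproduces the alternating 1.0/1.1 s pattern
        best = np.inf
        for par in (0, 1):
            det = np.diff(rec.t[ev.step_idx[par::2]])
            for phase in (0, 1):
                truth = durations[phase : phase + det.size]
                if truth.size == det.size:
                    best = min(best, float(np.max(np.abs(det - truth))))
        assert best < 0.03


class TestExciseTurns:
    def _walk_with_turn(self):
        sim = simulate_gait(GaitSimConfig(seed=9, n_strides=40, turn_every=None,
                                          perturbation_sd=0.02))
        rec = sim.recordings["trunk_L5"]
        ev = detect_heel_strikes(rec)
        return sim, rec, ev

    def test_turn_window_plus_guard_strides_removed(self):
        sim, rec, ev = self._walk_with_turn()
        n_all = ev.n_strides
        # mark a turn spanning detected strides 19-21 (three full strides)
        hs_t = rec.t[ev.heel_strike_idx]
        turns = TurnAnnotation([(hs_t[19] + 0.01, hs_t[22] - 0.01)])
        segments = excise_turns(rec, ev, turns)
        kept = sum(s.n_strides for s in segments)
        assert len(segments) == 2
        assert kept == n_all - 3 - 2  # turn strides + one guard on each side

    def test_no_turns_is_identity_on_strides(self):
        _, rec, ev = self._walk_with_turn()
        segments = excise_turns(rec, ev, None)
        assert len(segments) == 1
        assert segments[0].n_strides == ev.n_strides
        np.testing.assert_array_equal(segments[0].stride_bounds, ev.heel_strike_idx)

    def test_turn_at_start_leaves_trailing_segment(self):
        _, rec, ev = self._walk_with_turn()
        hs_t = rec.t[ev.heel_strike_idx]
        turns = TurnAnnotation([(hs_t[0], hs_t[2])])
        segments = excise_turns(rec, ev, turns)
        assert len(segments) == 1
        assert sum(s.n_strides for s in segments) == ev.n_strides - 3

    @pytest.mark.parametrize("start,dur", [(5, 2), (12, 3), (25, 1)])
    def test_stride_count_conservation(self, start, dur):
        sim = simulate_gait(GaitSimConfig(seed=13, n_strides=40, turn_every=None,
                                          perturbation_sd=0.02))
        rec = sim.recordings["trunk_L5"]
        ev = detect_heel_strikes(rec)
        hs_t = rec.t[ev.heel_strike_idx]
        turns = TurnAnnotation([(hs_t[start] + 1e-3, hs_t[start + dur] - 1e-3)])
        kept = sum(s.n_strides for s in excise_turns(rec, ev, turns))
        assert kept == ev.n_strides - dur - 2


class TestSelectAndResample:
    def test_150_strides_to_15000_points(self, default_walk):
        rec = trim_startup(default_walk.recordings["trunk_L5"], 300)
        ev = detect_heel_strikes(rec)
        segments = excise_turns(rec, ev, default_walk.turns)
        series = select_and_resample(rec, segments, 150, 100)
        for axis in ("ap", "v", "ml"):
            assert series[axis].x.size == 15000
            assert series[axis].n_strides == 150

    def test_sinusoid_amplitude_preserved(self):
        fs = 296.3
        n = int(200 * fs)
        t = np.arange(n) / fs
        s = np.sin(2 * np.pi * 0.955 * t)
        rec = AccelRecording("trunk_L5", fs, t, s, s.copy(), s.copy())
        bounds = np.arange(0, n - 1, int(fs / 0.955))
        from gaitlds import WalkSegment

        series = select_and_resample(rec, [WalkSegment(bounds)], 150, 100)
        assert abs(series["ap"].x.max() - 1.0) < 0.01
        assert abs(series["ap"].x.min() + 1.0) < 0.01

    def test_insufficient_strides_error_reports_count(self, short_walk):
        rec = short_walk.recordings["trunk_L5"]
        ev = detect_heel_strikes(rec)
        segments = excise_turns(rec, ev, None)
        with pytest.raises(GaitProcessingError, match=rf"{ev.n_strides} < 150"):
            select_and_resample(rec, segments, 150, 100)

    def test_idempotent_on_uniform_grid(self):
        # input already on a 100-samples-per-stride grid maps to itself
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        t = np.arange(2000) / 100.0
        rec = AccelRecording("trunk_L5", 100.0, t, x, x.copy(), x.copy())
        from gaitlds import WalkSegment

        seg = WalkSegment(np.arange(0, 2001, 100))
        series = select_and_resample(rec, [seg], 20, 100)
        np.testing.assert_allclose(series["ap"].x, x, atol=1e-9)


class TestStrideFrequency:
    def test_recovers_built_in_rate(self):
        sim = simulate_gait(GaitSimConfig(seed=1, perturbation_sd=0.02, turn_every=None))
        rec = trim_startup(sim.recordings["trunk_L5"], 300)
        assert stride_frequency(rec) == pytest.approx(0.955, abs=0.01)

    def test_pure_sinusoid(self):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        s = np.sin(2 * np.pi * 1.0 * t)
        rec = AccelRecording("trunk_L5", fs, t, s, s.copy(), s.copy())
        assert stride_frequency(rec) == pytest.approx(1.00, abs=0.01)

    def test_white_noise_has_no_dominant_peak(self, rng):
        fs = 100.0
        n = int(60 * fs)
        t = np.arange(n) / fs
        x = rng.normal(size=n)
        rec = AccelRecording("trunk_L5", fs, t, x, x.copy(), x.copy())
        with pytest.raises(GaitProcessingError, match="no dominant peak"):
            stride_frequency(rec)

    def test_segment_restricted_spectrum_ignores_turns(self, default_walk):
        rec = trim_startup(default_walk.recordings["trunk_L5"], 300)
        ev = detect_heel_strikes(rec)
        segments = excise_turns(rec, ev, default_walk.turns)
        f = stride_frequency(rec, segments=segments)
        assert f == pytest.approx(0.955, abs=0.015)


class TestGaitSpeed:
    def test_mean_of_interval_ratios(self):
        assert gait_speed([25.0, 25.0], [20.0, 20.0]) == pytest.approx(1.25)

    def test_single_interval(self):
        assert gait_speed([25.0], [20.833]) == pytest.approx(1.2000, abs=5e-4)

    def test_zero_time_rejected(self):
        with pytest.raises(GaitProcessingError):
            gait_speed([25.0], [0.0])
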