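import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcdetect.detector import (
    DetectorParams,
    apc_features,
    detect,
    find_variance_peaks,
    group_peaks,
    highpass,
    moving_variance,
)
from apcdetect.signal_io import AccelTrace, DepthTrace
from apcdetect.synthetic import burst_waveform
from oracles import brute_extent_integral, brute_groups, brute_moving_variance, brute_peaks

FS = 20.0


def sine_attenuation(freq, fs=FS, cutoff=3.0, n=4000):
    """Measured filtfilt amplitude ratio for a pure tone (middle section)."""
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = highpass(x, fs, cutoff)
    mid = slice(n // 4, 3 * n // 4)
    return np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))


class TestHighpass:
    def test_constant_input_removed(self):
        y = highpass(np.full(500, 2.5), FS)
        assert np.max(np.abs(y)) < 1e-6

    @pytest.mark.parametrize("freq,band", [(1.0, "stop"), (6.0, "pass")])
    def test_tone_attenuation_matches_analytic_response(self, freq, band):
        from scipy.signal import butter, sosfreqz

        ratio = sine_attenuation(freq)
        sos = butter(4, 3.0, btype="highpass", fs=FS, output="sos")
        _, h = sosfreqz(sos, worN=[freq], fs=FS)
        analytic = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
        assert ratio == pytest.approx(analytic, rel=0.05)
        if band == "stop":
            assert ratio < 0.10
        else:
            assert ratio > 0.90

    def test_zero_phase_no_timing_shift(self):
        t = np.arange(2000) / FS
        burst = np.zeros_like(t)
        w = burst_waveform(1.0, 6.0, 1.0, FS)
        burst[1000 : 1000 + len(w)] = w
        y = highpass(burst, FS)
        assert abs(int(np.argmax(np.abs(y))) - int(np.argmax(np.abs(burst)))) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass(np.zeros(100), FS, cutoff=10.0)


class TestMovingVariance:
    def test_constant_series_zero(self):
        v, _ = moving_variance(np.full(100, 3.3), 30)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        assert len(v) == 71

    def test_hand_computed_window(self):
        # var([1,1,1,3]) with the n-1 denominator is exactly 1.0
        v, off = moving_variance(np.array([1.0, 1.0, 1.0, 3.0]), 4)
        assert v[0] == pytest.approx(1.0)
        assert off == 1

    def test_short_series_empty(self):
        v, _ = moving_variance(np.arange(5, dtype=float), 30)
        assert len(v) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5, allow_nan=False), min_size=30, max_size=120),
        w=st.integers(2, 30),
    )
    def test_agrees_with_brute_force(self, x, w):
        x = np.asarray(x)
        v, _ = moving_variance(x, w)
        np.testing.assert_allclose(v, brute_moving_variance(x, w), atol=1e-8)


class TestFindVariancePeaks:
    def test_all_below_threshold_empty(self):
        assert len(find_variance_peaks(np.full(50, 0.05), 0.1)) == 0

    def test_triangular_bump_single_apex(self):
        v = np.concatenate([np.linspace(0, 1, 10), np.linspace(1, 0, 10)[1:]])
        peaks = find_variance_peaks(v, 0.1)
        assert list(peaks) == [9]

    def test_two_bumps_with_subthreshold_valley(self):
        v = np.concatenate(
            [np.linspace(0, 1, 6), np.linspace(1, 0.02, 6)[1:], np.linspace(0.02, 0.8, 6)[1:], np.linspace(0.8, 0, 6)[1:]]
        )
        assert len(find_variance_peaks(v, 0.1)) == 2

    def test_plateau_reports_first_sample(self):
        v = np.array([0.0, 0.5, 0.5, 0.5, 0.0])
        assert list(find_variance_peaks(v, 0.1)) == [1]

    def test_peak_at_threshold_not_strictly_above_excluded(self):
        v = np.array([0.0, 0.1, 0.0])
        assert len(find_variance_peaks(v, 0.1)) == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        v=st.lists(st.integers(0, 8), min_size=3, max_size=80),
        thr=st.integers(0, 6),
    )
    def test_agrees_with_brute_force(self, v, thr):
        # integer-valued series exercise plateaus heavily
        v = np.asarray(v, dtype=float) / 4.0
        np.testing.assert_array_equal(find_variance_peaks(v, thr / 4.0), brute_peaks(v, thr / 4.0))


class TestGroupPeaks:
    def test_chain_rule_example(self):
        groups = group_peaks(np.array([10.0, 13.0, 30.0]), 5.0)
        assert [list(g) for g in groups] == [[0, 1], [2]]

    def test_wide_interval_single_group(self):
        groups = group_peaks(np.array([10.0, 13.0, 30.0]), 20.0)
        assert [list(g) for g in groups] == [[0, 1, 2]]

    def test_empty_input(self):
        assert group_peaks(np.array([]), 5.0) == []

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(st.floats(0.1, 30, allow_nan=False), min_size=0, max_size=40),
        interval=st.floats(0.5, 25, allow_nan=False),
    )
    def test_agrees_with_brute_force(self, gaps, interval):
        times = np.cumsum([0.0] + gaps)
        groups = group_peaks(times, interval)
        expected = brute_groups(list(times), interval)
        assert [list(times[g]) for g in groups] == expected

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(gaps=st.lists(st.floats(0.1, 30, allow_nan=False), min_size=1, max_size=40))
    def test_group_count_non_increasing_in_interval(self, gaps):
        times = np.cumsum([0.0] + gaps)
        counts = [len(group_peaks(times, itv)) for itv in (2.0, 5.0, 10.0, 20.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestApcFeatures:
    def make_rect(self, height=0.2, width_s=2.0, fs=FS):
        n = int(width_s * fs) + 1
        v = np.concatenate([np.zeros(20), np.full(n, height), np.zeros(20)])
        t = np.arange(len(v)) / fs
        return v, t

    def test_rectangle_pulse_arithmetic(self):
        v, t = self.make_rect()
        peaks = find_variance_peaks(v, 0.1)
        apc = apc_features(peaks, v, t, 0.1, dive_id=0, axis="surge")
        assert apc.n_peaks == 1
        assert apc.duration == pytest.approx(2.0)
        assert apc.integral_area == pytest.approx(0.4)  # 0.2 g^2 x 2 s

    def test_sample_sum_mode(self):
        v, t = self.make_rect()
        peaks = find_variance_peaks(v, 0.1)
        apc = apc_features(peaks, v, t, 0.1, dive_id=0, axis="surge", integral_mode="sample_sum")
        assert apc.integral_area == pytest.approx(0.2 * 41)

    def test_two_pulse_additivity(self):
        v1, t1 = self.make_rect()
        gap = np.zeros(40)
        v = np.concatenate([v1, gap, v1])
        t = np.arange(len(v)) / FS
        peaks = find_variance_peaks(v, 0.1)
        apc = apc_features(peaks, v, t, 0.1, dive_id=0, axis="surge")
        assert apc.n_peaks == 2
        assert apc.integral_area == pytest.approx(0.8)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(v=st.lists(st.floats(0, 1, allow_nan=False), min_size=10, max_size=100))
    def test_agrees_with_brute_force(self, v):
        v = np.asarray(v)
        t = np.arange(len(v)) / FS
        peaks = find_variance_peaks(v, 0.3)
        if len(peaks) == 0:
            return
        apc = apc_features(peaks, v, t, 0.3, dive_id=0, axis="surge")
        dur, area = brute_extent_integral(v, t, list(peaks), 0.3)
        assert apc.duration == pytest.approx(dur)
        assert apc.integral_area == pytest.approx(area)


def make_burst_dive(burst_times, fs=FS, depth_max=60.0, total=300.0, amplitude=1.5, gap_burst=1.0):
    """One trapezoidal dive with noiseless bursts at given times."""
    n = int(total * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt in burst_times:
        w = burst_waveform(gap_burst, 6.0, amplitude, fs)
        i0 = int(bt * fs)
        x[i0 : i0 + len(w)] += w
    knots_t = [0, 20, 60, 240, 280, total]
    knots_d = [0, 0, depth_max, depth_max, 0, 0]
    d = np.interp(t, knots_t, knots_d)
    accel = AccelTrace(0.0, fs, x, np.zeros(n), np.zeros(n), clip_limit=3.0)
    depth = DepthTrace(0.0, fs, d)
    return accel, depth


class TestDetect:
    def dives_for(self, depth):
        from apcdetect.dives import find_dives

        return find_dives(depth)

    def test_three_separated_bursts_three_apc(self):
        accel, depth = make_burst_dive([100.0, 130.0, 170.0])
        dives = self.dives_for(depth)
        dets = detect(accel, depth, dives, DetectorParams())
        assert len(dets) == 3
        for det, expected in zip(dets, [100.0, 130.0, 170.0]):
            assert det.t_first_peak == pytest.approx(expected + 0.5, abs=1.0)

    def test_no_bursts_no_apc(self):
        accel, depth = make_burst_dive([])
        assert detect(accel, depth, self.dives_for(depth), DetectorParams()) == []

    def test_two_close_bursts_group_into_one_apc(self):
        accel, depth = make_burst_dive([100.0, 103.0])
        dets = detect(accel, depth, self.dives_for(depth), DetectorParams(min_interval=5.0))
        assert len(dets) == 1
        assert dets[0].n_peaks >= 2

    def test_variance_level_two_peak_grouping(self):
        # two triangular variance bumps 3 s apart, 5 s interval -> one APC, 2 peaks
        bump = np.concatenate([np.linspace(0, 0.5, 11), np.linspace(0.5, 0, 11)[1:]])
        v = np.concatenate([np.zeros(10), bump, np.zeros(int(3 * FS) - len(bump)), bump, np.zeros(10)])
        t = np.arange(len(v)) / FS
        peaks = find_variance_peaks(v, 0.1)
        groups = group_peaks(t[peaks], 5.0)
        assert len(groups) == 1
        apc = apc_features(peaks[groups[0]], v, t, 0.1, dive_id=0, axis="surge")
        assert apc.n_peaks == 2

    def test_detection_count_monotone_in_threshold(self):
        accel, depth = make_burst_dive([100.0, 130.0, 170.0], amplitude=1.0)
        dives = self.dives_for(depth)
        counts = [
            len(detect(accel, depth, dives, DetectorParams(variance_threshold=thr)))
            for thr in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_shift_equivariance(self):
        accel, depth = make_burst_dive([100.0, 150.0])
        dives = self.dives_for(depth)
        base = detect(accel, depth, dives, DetectorParams())
        delta = 0.5
        accel2 = AccelTrace(delta, accel.sample_rate, accel.surge, accel.sway, accel.heave)
        depth2 = DepthTrace(delta, depth.sample_rate, depth.depth)
        from apcdetect.dives import find_dives

        shifted = detect(accel2, depth2, find_dives(depth2), DetectorParams())
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert b.t_first_peak == pytest.approx(a.t_first_peak + delta, abs=1e-9)

    def test_peaks_lie_inside_dive_below_surface_exclusion(self, clean_deployment):
        dep, _, _ = clean_deployment
        dets = detect(dep.accel, dep.depth_hi, dep.dives, DetectorParams())
        by_id = {d.dive_id: d for d in dep.dives}
        fs = dep.accel.sample_rate
        for det in dets:
            dive = by_id[det.dive_id]
            for pt in det.peak_times:
                assert dive.start <= pt <= dive.end
                i = int(round((pt - dep.depth_hi.start_time) * fs))
                assert dep.depth_hi.depth[i] > 2.0

    def test_dive_shorter_than_window_yields_none(self):
        accel, depth = make_burst_dive([])
        from apcdetect.dives import Dive

        tiny = Dive(0, 100.0, 100.6, 60.0, 100.2, 100.4)
        assert detect(accel, depth, [tiny], DetectorParams()) == []
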