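import numpy as np
import pytest

from apcdetect.signal_io import (
    AccelTrace,
    ClockOffset,
    DepthTrace,
    TraceParseError,
    align_streams,
    apply_offset,
    estimate_clock_offset,
    read_accel,
    read_depth,
    upsample_depth,
    write_accel,
    write_depth,
)


def make_accel(n=100, rate=20.0, start=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return AccelTrace(start, rate, *rng.normal(0, 0.5, (3, n)), clip_limit=3.0)


class TestTraceContainers:
    def test_axis_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            AccelTrace(0.0, 20.0, np.zeros(3), np.zeros(3), np.zeros(4))

    def test_clip_limit_enforced(self):
        with pytest.raises(ValueError, match="clip limit"):
            AccelTrace(0.0, 20.0, np.array([3.5]), np.array([0.0]), np.array([0.0]))

    def test_times_grid(self):
        tr = make_accel(n=5, rate=20.0, start=10.0)
        assert np.allclose(tr.times(), 10.0 + np.arange(5) / 20.0)


class TestRoundTrip:
    def test_accel_round_trip_exact(self, tmp_path):
        tr = make_accel(n=50)
        write_accel(tr, tmp_path / "a.csv")
        back = read_accel(tmp_path / "a.csv")
        for ax in ("surge", "sway", "heave"):
            np.testing.assert_array_equal(back.axis(ax), tr.axis(ax))
        assert back.sample_rate == tr.sample_rate
        assert back.start_time == pytest.approx(tr.start_time, abs=1e-6)

    def test_depth_round_trip_exact(self, tmp_path):
        tr = DepthTrace(5.0, 1.0, np.array([0.0, 10.5, 63.25, 2.0]))
        write_depth(tr, tmp_path / "d.csv")
        back = read_depth(tmp_path / "d.csv")
        np.testing.assert_array_equal(back.depth, tr.depth)

    def test_three_row_fixture(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "# start_time: 1970-01-01T00:00:00+00:00\n"
            "# sample_rate_hz: 20.0\n"
            "t_s,surge,sway,heave\n0.0,0.1,0.2,0.3\n0.05,0.1,0.2,0.3\n0.1,0.1,0.2,0.3\n"
        )
        assert read_accel(tmp_path / "a.csv").n_samples == 3

    def test_timestamp_gap_reported_with_location(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "# start_time: 1970-01-01T00:00:00+00:00\n"
            "# sample_rate_hz: 20.0\n"
            "t_s,surge,sway,heave\n0.0,0,0,0\n0.05,0,0,0\n0.50,0,0,0\n"
        )
        with pytest.raises(TraceParseError, match="row 2"):
            read_accel(tmp_path / "a.csv")

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "# start_time: 1970-01-01T00:00:00+00:00\n# sample_rate_hz: 20.0\n"
            "t_s,surge,sway\n0.0,0,0\n"
        )
        with pytest.raises(TraceParseError, match="heave"):
            read_accel(tmp_path / "a.csv")

    def test_malformed_row_line_number(self, tmp_path):
        (tmp_path / "d.csv").write_text(
            "# start_time: 1970-01-01T00:00:00+00:00\n# sample_rate_hz: 1.0\n"
            "t_s,depth_m\n0.0,1.0\n1.0,\n"
        )
        with pytest.raises(TraceParseError, match="line"):
            read_depth(tmp_path / "d.csv")


class TestClockOffset:
    def test_zero_offset_is_identity(self):
        tr = make_accel()
        assert apply_offset(tr, ClockOffset(0.0)) is tr

    def test_offset_then_inverse_restores_start(self):
        tr = make_accel(start=100.0)
        shifted = apply_offset(tr, ClockOffset(1.0))
        assert shifted.start_time == 101.0
        back = apply_offset(shifted, ClockOffset(-1.0), allow_reapply=True)
        assert back.start_time == tr.start_time
        np.testing.assert_array_equal(back.surge, tr.surge)

    def test_double_application_guarded(self):
        tr = apply_offset(make_accel(), ClockOffset(1.0))
        with pytest.raises(ValueError, match="already applied"):
            apply_offset(tr, ClockOffset(1.0))

    def test_non_finite_offset_rejected(self):
        with pytest.raises(ValueError):
            ClockOffset(float("nan"))


class TestUpsampleDepth:
    def test_linear_midpoint(self):
        up = upsample_depth(DepthTrace(0.0, 1.0, np.array([10.0, 20.0])), 2.0)
        assert up.depth[1] == pytest.approx(15.0)

    def test_constant_stays_constant(self):
        up = upsample_depth(DepthTrace(0.0, 1.0, np.full(5, 7.0)), 20.0)
        np.testing.assert_array_equal(up.depth, np.full(81, 7.0))

    def test_length_and_endpoint_preservation(self):
        d = np.array([0.0, 3.0, 1.5, 8.0])
        up = upsample_depth(DepthTrace(0.0, 1.0, d), 20.0)
        assert up.n_samples == (len(d) - 1) * 20 + 1
        np.testing.assert_array_equal(up.depth[::20], d)

    def test_exact_on_affine_profile(self):
        # linear interpolation must reproduce a straight line exactly
        d = 2.5 * np.arange(6) + 1.0
        up = upsample_depth(DepthTrace(0.0, 1.0, d), 4.0)
        expected = 2.5 * (np.arange(up.n_samples) / 4.0) + 1.0
        np.testing.assert_allclose(up.depth, expected, atol=1e-12)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            upsample_depth(DepthTrace(0.0, 1.0, np.zeros(4)), 2.5)


class TestAlignStreams:
    def test_identical_spans_unchanged(self):
        a = make_accel(n=100)
        d = DepthTrace(0.0, 20.0, np.zeros(100))
        a2, d2 = align_streams(a, d)
        assert a2.n_samples == d2.n_samples == 100
        np.testing.assert_array_equal(a2.surge, a.surge)

    def test_accel_starting_earlier_drops_leading_samples(self):
        # accel starts 2 s before depth at 20 Hz -> first 40 samples dropped
        a = make_accel(n=200, start=0.0)
        d = DepthTrace(2.0, 20.0, np.zeros(200))
        a2, d2 = align_streams(a, d)
        assert a2.start_time == pytest.approx(2.0)
        np.testing.assert_array_equal(a2.surge, a.surge[40:])
        assert a2.n_samples == d2.n_samples

    def test_no_overlap_raises(self):
        a = make_accel(n=20, start=0.0)
        d = DepthTrace(100.0, 20.0, np.zeros(20))
        with pytest.raises(ValueError, match="overlap"):
            align_streams(a, d)

    def test_short_overlap_warns_then_raises(self):
        a = make_accel(n=40, start=0.0)
        d = DepthTrace(1.5, 20.0, np.zeros(40))
        with pytest.warns(UserWarning, match="overlap"):
            with pytest.raises(ValueError, match="too short"):
                align_streams(a, d, min_overlap=1.5)


def test_cross_correlation_offset_recovery():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 2000)
    lag = 30  # b delayed by 1.5 s at 20 Hz
    b = np.roll(x, lag)
    est = estimate_clock_offset(x, b, 20.0, max_lag=5.0)
    assert est == pytest.approx(-1.5, abs=0.05)
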