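"""Sensor time-series containers and tabular I/O.

Two instruments are modelled: a head-mounted tri-axial accelerometer
(surge = anterior-posterior, sway = lateral, heave = dorsal-ventral,
typically 20 Hz, hard-clipped at the logger gain limit of +/-3 g) and a
time-depth recorder (TDR, typically 1 Hz, metres positive downward).

Traces are stored on a uniform grid: an absolute start time (seconds on a
shared deployment clock), a sample rate, and per-axis sample arrays.  Files
are self-describing CSVs with a ``#``-prefixed metadata header (ISO-8601
start time, sample rate, clip limit) followed by one row per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "DepthTrace",
    "ClockOffset",
    "TraceParseError",
    "read_accel",
    "write_accel",
    "read_depth",
    "write_depth",
    "apply_offset",
    "upsample_depth",
    "align_streams",
    "estimate_clock_offset",
]

# Seconds tolerated between declared and observed sample spacing before a
# row is called a gap: half a sample period absorbs logger export rounding.
_UNIFORMITY_FRACTION = 0.5

_EPOCH = pd.Timestamp("1970-01-01T00:00:00+00:00")


class TraceParseError(ValueError):
    """Malformed trace file (missing columns, bad rows, timestamp gaps)."""


def _check_axes(*axes: np.ndarray) -> None:
    n = {len(a) for a in axes}
    if len(n) != 1:
        raise ValueError(f"axes have unequal lengths: {sorted(n)}")


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g."""

    start_time: float
    sample_rate: float
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    clip_limit: float | None = 3.0
    offset_applied: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("surge", "sway", "heave"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_axes(self.surge, self.sway, self.heave)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.clip_limit is not None:
            top = max(
                (float(np.max(np.abs(a))) for a in (self.surge, self.sway, self.heave) if len(a)),
                default=0.0,
            )
            if top > self.clip_limit + 1e-9:
                raise ValueError(
                    f"sample magnitude {top:.4f} g exceeds clip limit {self.clip_limit} g"
                )

    @property
    def n_samples(self) -> int:
        return len(self.surge)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.sample_rate if self.n_samples else self.start_time

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def axis(self, name: str) -> np.ndarray:
        if name not in ("surge", "sway", "heave"):
            raise KeyError(f"unknown axis {name!r}; expected surge, sway or heave")
        return getattr(self, name)


@dataclass(frozen=True)
class DepthTrace:
    """Uniformly sampled depth in metres, positive downward."""

    start_time: float
    sample_rate: float
    depth: np.ndarray
    offset_applied: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.depth)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.sample_rate if self.n_samples else self.start_time

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class ClockOffset:
    """Constant number of seconds to add to one stream's timestamps.

    The instruments run on independent clocks; dives whose streams cannot be
    brought within about a second of each other by a constant shift should be
    excluded upstream (time-varying drift is not modelled).
    """

    seconds: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.seconds):
            raise ValueError("clock offset must be finite")


def apply_offset(trace, offset: ClockOffset, allow_reapply: bool = False):
    """Shift a trace's start time by ``offset.seconds``; samples untouched.

    A correction is meant to be applied at most once per stream, so a second
    application raises unless ``allow_reapply`` is set explicitly (e.g. to
    revert a shift).  Identity offsets (0 s) do not mark the stream shifted.
    """
    if offset.seconds == 0.0:
        return trace
    if trace.offset_applied and not allow_reapply:
        raise ValueError("a clock offset was already applied to this stream")
    return replace(trace, start_time=trace.start_time + offset.seconds, offset_applied=True)


# ---------------------------------------------------------------------------
# file format


def _iso(seconds: float) -> str:
    return (_EPOCH + pd.to_timedelta(seconds, unit="s")).isoformat()


def _from_iso(text: str) -> float:
    return (pd.Timestamp(text) - _EPOCH).total_seconds()


def _write_table(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def _read_table(path, required: list[str]) -> tuple[dict, pd.DataFrame, int]:
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    try:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                n_header += 1
    except OSError as exc:
        raise TraceParseError(f"{path}: cannot read ({exc})") from exc
    try:
        frame = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    except Exception as exc:
        raise TraceParseError(f"{path}: cannot parse CSV body ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing}")
    bad = frame[required].isna().any(axis=1)
    if bad.any():
        # +2: 1-based line numbering plus the column-header line
        lines = [int(i) + n_header + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise TraceParseError(f"{path}: malformed row(s) at line(s) {lines}")
    return meta, frame, n_header


def _check_uniform(path, t: np.ndarray, rate: float, n_header: int) -> None:
    if len(t) < 2:
        return
    period = 1.0 / rate
    expected = t[0] + np.arange(len(t)) * period
    off = np.abs(t - expected)
    bad = np.flatnonzero(off > _UNIFORMITY_FRACTION * period)
    if len(bad):
        i = int(bad[0])
        raise TraceParseError(
            f"{path}: non-uniform timestamps: row {i} (line {i + n_header + 2}) is "
            f"{t[i] - expected[i]:+.3f} s off the {rate} Hz grid"
        )


def write_accel(trace: AccelTrace, path) -> None:
    meta = {
        "apcdetect": "accel-trace v1",
        "start_time": _iso(trace.start_time),
        "sample_rate_hz": repr(float(trace.sample_rate)),
        "clip_limit_g": "none" if trace.clip_limit is None else repr(float(trace.clip_limit)),
    }
    rel = np.arange(trace.n_samples) / trace.sample_rate
    frame = pd.DataFrame(
        {"t_s": rel, "surge": trace.surge, "sway": trace.sway, "heave": trace.heave}
    )
    _write_table(path, meta, frame)


def read_accel(path) -> AccelTrace:
    meta, frame, n_header = _read_table(path, ["t_s", "surge", "sway", "heave"])
    try:
        start = _from_iso(meta["start_time"])
        rate = float(meta["sample_rate_hz"])
    except (KeyError, ValueError) as exc:
        raise TraceParseError(f"{path}: bad or missing metadata header ({exc})") from exc
    clip = meta.get("clip_limit_g", "none")
    clip_limit = None if clip == "none" else float(clip)
    _check_uniform(path, frame["t_s"].to_numpy(), rate, n_header)
    return AccelTrace(
        start_time=start,
        sample_rate=rate,
        surge=frame["surge"].to_numpy(),
        sway=frame["sway"].to_numpy(),
        heave=frame["heave"].to_numpy(),
        clip_limit=clip_limit,
    )


def write_depth(trace: DepthTrace, path) -> None:
    meta = {
        "apcdetect": "depth-trace v1",
        "start_time": _iso(trace.start_time),
        "sample_rate_hz": repr(float(trace.sample_rate)),
    }
    rel = np.arange(trace.n_samples) / trace.sample_rate
    _write_table(path, meta, pd.DataFrame({"t_s": rel, "depth_m": trace.depth}))


def read_depth(path) -> DepthTrace:
    meta, frame, n_header = _read_table(path, ["t_s", "depth_m"])
    try:
        start = _from_iso(meta["start_time"])
        rate = float(meta["sample_rate_hz"])
    except (KeyError, ValueError) as exc:
        raise TraceParseError(f"{path}: bad or missing metadata header ({exc})") from exc
    _check_uniform(path, frame["t_s"].to_numpy(), rate, n_header)
    return DepthTrace(start_time=start, sample_rate=rate, depth=frame["depth_m"].to_numpy())


# ---------------------------------------------------------------------------
# resampling and alignment


def upsample_depth(depth: DepthTrace, target: float) -> DepthTrace:
    """Linearly interpolate a depth trace to ``target`` Hz.

    ``target`` must be an integer multiple of the source rate (the 1 Hz TDR
    record is brought onto the 20 Hz accelerometer grid).  Original samples
    are preserved exactly; interior samples interpolate linearly.
    """
    ratio = target / depth.sample_rate
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target rate {target} Hz is not an integer multiple of source {depth.sample_rate} Hz"
        )
    if factor == 1 or depth.n_samples < 2:
        return DepthTrace(depth.start_time, target, depth.depth.copy())
    d = depth.depth
    n_out = (len(d) - 1) * factor + 1
    out = np.empty(n_out)
    frac = np.arange(factor) / factor  # first entry 0 -> knots copied verbatim
    seg = d[:-1, None] + (d[1:] - d[:-1])[:, None] * frac[None, :]
    out[: n_out - 1] = seg.ravel()
    out[-1] = d[-1]
    return DepthTrace(depth.start_time, target, out)


def align_streams(
    accel: AccelTrace,
    depth: DepthTrace,
    min_overlap: float | None = None,
) -> tuple[AccelTrace, DepthTrace]:
    """Trim both streams to their common time window on a shared grid.

    Both streams must already be at the same rate (upsample depth first).
    Raises if the streams do not overlap; if the overlap is shorter than
    ``min_overlap`` seconds a warning is issued and an error raised, since a
    window too short for the detector's variance window is unusable.
    """
    if abs(accel.sample_rate - depth.sample_rate) > 1e-9:
        raise ValueError("streams must share a sample rate before alignment")
    rate = accel.sample_rate
    start = max(accel.start_time, depth.start_time)
    end = min(accel.end_time, depth.end_time)
    if end < start:
        raise ValueError(
            f"streams do not overlap (accel ends {accel.end_time:.2f}, depth ends {depth.end_time:.2f})"
        )
    if min_overlap is not None and end - start < min_overlap:
        warnings.warn(
            f"stream overlap {end - start:.2f} s shorter than required {min_overlap} s",
            stacklevel=2,
        )
        raise ValueError(f"stream overlap {end - start:.2f} s too short")

    def trim(trace):
        i0 = int(round((start - trace.start_time) * rate))
        i1 = int(round((end - trace.start_time) * rate)) + 1
        return i0, i1

    a0, a1 = trim(accel)
    d0, d1 = trim(depth)
    n = min(a1 - a0, d1 - d0)
    accel_out = AccelTrace(
        start_time=accel.start_time + a0 / rate,
        sample_rate=rate,
        surge=accel.surge[a0 : a0 + n],
        sway=accel.sway[a0 : a0 + n],
        heave=accel.heave[a0 : a0 + n],
        clip_limit=accel.clip_limit,
    )
    depth_out = DepthTrace(
        start_time=depth.start_time + d0 / rate,
        sample_rate=rate,
        depth=depth.depth[d0 : d0 + n],
    )
    return accel_out, depth_out


def estimate_clock_offset(a: np.ndarray, b: np.ndarray, sample_rate: float, max_lag: float) -> float:
    """Cross-correlation estimate of the lag of ``b`` relative to ``a``, in s.

    Helper only: the pipeline never applies an offset implicitly, mirroring a
    workflow where stream alignment is checked by eye.  Positive return means
    ``b`` starts later and ``ClockOffset(+value)`` applied to ``b``'s clock
    aligns it with ``a``.
    """
    from scipy.signal import correlate, correlation_lags

    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    corr = correlate(a, b, mode="full")
    lags = correlation_lags(len(a), len(b), mode="full")
    max_lag_samples = int(round(max_lag * sample_rate))
    keep = np.abs(lags) <= max_lag_samples
    best = lags[keep][np.argmax(corr[keep])]
    return float(best) / sample_rate
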