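"""Attempted-prey-capture (APC) detection from head acceleration.

The detector isolates rapid head movements with a zero-phase high-pass
filter (default 3 Hz: swimming strokes sit near 1-1.5 Hz, strike/handling
bursts above 3 Hz), computes the sample variance of the filtered signal in
a moving 1.5 s window within each dive (surface samples excluded), marks
local maxima of the variance above a threshold, chains peaks closer than a
minimum interval into one APC, and summarises each APC by the time of its
first peak, its duration, its peak count and the integral area under the
variance curve.

Two free parameters — the variance threshold (g^2) and the minimum interval
(s) — are what the holdout optimisation in :mod:`apcdetect.optimize` tunes;
the canonical grids are {0.1, 0.2, 0.4, 0.8} x {5, 10, 20 s} (the heave
axis, whose bursts are weaker, drops the 0.8 threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .dives import Dive
from .signal_io import AccelTrace, DepthTrace

__all__ = [
    "DetectorParams",
    "DetectedAPC",
    "highpass",
    "moving_variance",
    "find_variance_peaks",
    "group_peaks",
    "apc_features",
    "DiveVariance",
    "build_variance_cache",
    "detect_from_cache",
    "detect",
    "SURGE_SWAY_THRESHOLDS",
    "HEAVE_THRESHOLDS",
    "MIN_INTERVALS",
    "GENERIC_THRESHOLD",
    "GENERIC_MIN_INTERVAL",
]

logger = logging.getLogger(__name__)

SURGE_SWAY_THRESHOLDS = (0.1, 0.2, 0.4, 0.8)
HEAVE_THRESHOLDS = (0.1, 0.2, 0.4)
MIN_INTERVALS = (5.0, 10.0, 20.0)
GENERIC_THRESHOLD = 0.1
GENERIC_MIN_INTERVAL = 5.0


@dataclass(frozen=True)
class DetectorParams:
    """Detector settings for one acceleration axis.

    ``integral_mode`` selects the units of the per-APC area: ``"time"``
    integrates the variance curve over its supra-threshold extents
    (trapezoidal, g^2 s, the default) while ``"sample_sum"`` sums the raw
    variance samples (g^2), matching reports that quote the area in g^2.
    """

    axis: str = "surge"
    cutoff: float = 3.0
    variance_window: float = 1.5
    variance_threshold: float = GENERIC_THRESHOLD
    min_interval: float = GENERIC_MIN_INTERVAL
    integral_mode: str = "time"

    def __post_init__(self) -> None:
        if self.axis not in ("surge", "sway", "heave"):
            raise ValueError(f"axis must be surge, sway or heave, got {self.axis!r}")
        for name in ("cutoff", "variance_window", "variance_threshold", "min_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.integral_mode not in ("time", "sample_sum"):
            raise ValueError("integral_mode must be 'time' or 'sample_sum'")

    def with_(self, **kw) -> "DetectorParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DetectedAPC:
    """One detected attempted prey capture on one axis of one dive."""

    dive_id: int
    axis: str
    t_first_peak: float
    duration: float
    n_peaks: int
    integral_area: float
    peak_times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("an APC contains at least one variance peak")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


# ---------------------------------------------------------------------------
# signal primitives


def highpass(x: np.ndarray, sample_rate: float, cutoff: float = 3.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass (forward-backward) of one axis.

    Forward-backward filtering keeps event timing unshifted, which matters
    because detections are matched to annotated video windows by time.
    """
    if cutoff >= sample_rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {sample_rate / 2} Hz")
    sos = butter(order, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def moving_variance(x: np.ndarray, window_samples: int) -> tuple[np.ndarray, int]:
    """Centred moving sample variance (n-1 denominator).

    Returns ``(var, offset)`` where ``var[k]`` is the variance of
    ``x[k : k + window_samples]`` and ``offset = (window_samples - 1) // 2``
    maps ``var[k]`` to its centre sample ``x[k + offset]``.  Positions whose
    window would run past the data are excluded, so the output is shorter
    than the input by ``window_samples - 1`` (empty if the series is shorter
    than the window).
    """
    x = np.asarray(x, dtype=float)
    w = int(window_samples)
    if w < 2:
        raise ValueError("variance window must span at least 2 samples")
    if len(x) < w:
        return np.empty(0), (w - 1) // 2
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = (s2 - s1 * s1 / w) / (w - 1)
    np.maximum(var, 0.0, out=var)  # guard tiny negative round-off
    return var, (w - 1) // 2


def find_variance_peaks(var: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of local variance maxima strictly above ``threshold``.

    A peak is a sample (or plateau of equal samples) strictly greater than
    its neighbours on both sides; plateaus report their first sample.
    Series endpoints cannot be peaks.
    """
    if len(var) < 3:
        return np.empty(0, dtype=int)
    peaks, props = find_peaks(var, plateau_size=1)
    left = props["left_edges"]
    return left[var[left] > threshold]


def group_peaks(peak_times: np.ndarray, min_interval: float) -> list[np.ndarray]:
    """Chain time-sorted peaks into APC groups.

    Consecutive peaks no more than ``min_interval`` apart belong to one APC
    (a single capture often produces several variance peaks, e.g. strike
    then handling); a gap greater than the interval starts a new APC.
    Returns a list of index arrays into ``peak_times``.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    n = len(peak_times)
    if n == 0:
        return []
    splits = np.flatnonzero(np.diff(peak_times) > min_interval) + 1
    return np.split(np.arange(n), splits)


def _extents(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs (start, stop-exclusive) of a boolean mask."""
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if len(above) and above[0]:
        starts.insert(0, 0)
    if len(above) and above[-1]:
        stops.append(len(above))
    return list(zip(starts, stops))


def apc_features(
    group: np.ndarray,
    var: np.ndarray,
    t: np.ndarray,
    threshold: float,
    *,
    dive_id: int,
    axis: str,
    integral_mode: str = "time",
) -> DetectedAPC:
    """Summarise one peak group into a :class:`DetectedAPC`.

    ``group`` holds indices into ``var``/``t`` of the group's peaks.  The
    APC's duration and integral area are measured over the supra-threshold
    extents of the variance curve containing those peaks (the bracketed
    regions of a variance trace, merged across the group's peaks), not
    merely first-to-last peak time.
    """
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise ValueError("empty peak group")
    above = var > threshold
    runs = _extents(above)
    covering: list[tuple[int, int]] = []
    for p in group:
        for run in runs:
            if run[0] <= p < run[1]:
                if run not in covering:
                    covering.append(run)
                break
    if not covering:  # cannot happen for peaks above threshold; keep defensive
        covering = [(int(group[0]), int(group[0]) + 1)]
    first = min(r[0] for r in covering)
    last = max(r[1] for r in covering) - 1
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    if integral_mode == "time":
        area = float(sum(np.trapezoid(var[a:b], dx=dt) for a, b in covering))
    else:
        area = float(sum(var[a:b].sum() for a, b in covering))
    peak_t = tuple(float(t[p]) for p in group)
    return DetectedAPC(
        dive_id=dive_id,
        axis=axis,
        t_first_peak=float(t[group[0]]),
        duration=float(t[last] - t[first]),
        n_peaks=len(group),
        integral_area=area,
        peak_times=peak_t,
    )


# ---------------------------------------------------------------------------
# per-dive pipeline


@dataclass(frozen=True)
class DiveVariance:
    """Moving-variance series of one dive's sub-surface samples on one axis.

    Computing this once per dive lets a parameter grid search vary the
    variance threshold and minimum interval without re-filtering.
    """

    dive_id: int
    t: np.ndarray  # times of variance samples (window centres)
    var: np.ndarray


def build_variance_cache(
    accel: AccelTrace,
    depth: DepthTrace,
    dives: list[Dive],
    params: DetectorParams = DetectorParams(),
    surface_exclusion: float = 2.0,
) -> list[DiveVariance]:
    """High-pass the chosen axis and compute each dive's variance series.

    ``depth`` must be on the accelerometer grid (upsample first).  Within a
    dive only samples deeper than ``surface_exclusion`` metres enter the
    variance analysis.  Dives shorter than the variance window yield an
    empty series (logged).
    """
    if abs(accel.sample_rate - depth.sample_rate) > 1e-9 or accel.n_samples != depth.n_samples:
        raise ValueError("accel and depth must be aligned on a shared grid (align_streams)")
    fs = accel.sample_rate
    filtered = highpass(accel.axis(params.axis), fs, params.cutoff)
    w = int(round(params.variance_window * fs))
    t_all = accel.times()
    out = []
    for dive in dives:
        i0 = int(np.ceil((dive.start - accel.start_time) * fs))
        i1 = int(np.floor((dive.end - accel.start_time) * fs)) + 1
        i0, i1 = max(i0, 0), min(i1, accel.n_samples)
        deep = depth.depth[i0:i1] > surface_exclusion
        idx = np.flatnonzero(deep)
        if len(idx) < w:
            logger.info("dive %d shorter than variance window; no APC search", dive.dive_id)
            out.append(DiveVariance(dive.dive_id, np.empty(0), np.empty(0)))
            continue
        j0, j1 = i0 + idx[0], i0 + idx[-1] + 1
        var, off = moving_variance(filtered[j0:j1], w)
        t = t_all[j0 + off : j0 + off + len(var)]
        out.append(DiveVariance(dive.dive_id, t, var))
    return out


def detect_from_cache(
    cache: list[DiveVariance],
    params: DetectorParams,
) -> list[DetectedAPC]:
    """Peak detection, grouping and feature extraction on cached variances."""
    detections: list[DetectedAPC] = []
    for dv in cache:
        peaks = find_variance_peaks(dv.var, params.variance_threshold)
        groups = group_peaks(dv.t[peaks], params.min_interval)
        for g in groups:
            detections.append(
                apc_features(
                    peaks[g],
                    dv.var,
                    dv.t,
                    params.variance_threshold,
                    dive_id=dv.dive_id,
                    axis=params.axis,
                    integral_mode=params.integral_mode,
                )
            )
    return detections


def detect(
    accel: AccelTrace,
    depth: DepthTrace,
    dives: list[Dive],
    params: DetectorParams = DetectorParams(),
    surface_exclusion: float = 2.0,
) -> list[DetectedAPC]:
    """Full per-dive APC detection on one axis.

    Pipeline: high-pass -> per-dive moving variance (surface excluded) ->
    supra-threshold local maxima -> minimum-interval grouping -> per-APC
    features.  Returns all detections in time order.
    """
    cache = build_variance_cache(accel, depth, dives, params, surface_exclusion)
    return detect_from_cache(cache, params)


def count_per_dive(detections: list[DetectedAPC], dives: list[Dive]) -> dict[int, int]:
    """APC count per dive (dives with no detections report 0)."""
    counts = {dive.dive_id: 0 for dive in dives}
    for det in detections:
        counts[det.dive_id] = counts.get(det.dive_id, 0) + 1
    return counts
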