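"""Dive segmentation from time-depth records.

Depth is first zero-offset corrected (pressure sensors drift, so raw
"surface" readings wander away from 0 m), then excursions past a minimum
dive depth are extracted, and each dive is split into descent, bottom and
ascent phases from changes in the depth slope.

Defaults follow benthic-foraging fur seal deployments on a shallow shelf:
dives count from 15 m, the top 2 m are treated as surface, and maximum
depths fall in the 61-86 m range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .signal_io import DepthTrace

__all__ = ["Dive", "DiveParams", "zero_offset_correct", "find_dives", "split_phases", "dives_to_frame"]


@dataclass(frozen=True)
class DiveParams:
    """Segmentation thresholds.

    min_dive_depth
        metres a depth excursion must reach to count as a dive (default 15).
    surface_exclusion_depth
        metres above which samples are treated as surface and excluded from
        acceleration-variance analysis (default 2).
    zoc_window
        seconds of rolling-minimum window for zero-offset correction; must
        span at least one surfacing per window, i.e. exceed the longest dive.
    phase_speed_fraction
        a dive's descent ends (ascent starts) where vertical speed first
        (last) drops below this fraction of the dive's peak vertical speed.
    """

    min_dive_depth: float = 15.0
    surface_exclusion_depth: float = 2.0
    zoc_window: float = 600.0
    phase_speed_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (self.min_dive_depth > self.surface_exclusion_depth > 0):
            raise ValueError("require min_dive_depth > surface_exclusion_depth > 0")
        if self.zoc_window <= 0 or not (0 < self.phase_speed_fraction < 1):
            raise ValueError("zoc_window must be positive and phase_speed_fraction in (0,1)")


@dataclass(frozen=True)
class Dive:
    """One depth excursion below the dive threshold.

    ``start``/``end`` are the surface-exclusion-depth crossings bracketing
    the excursion; ``descent_end``/``ascent_start`` bound the bottom phase
    (equal for a V-dive with no bottom time).
    """

    dive_id: int
    start: float
    end: float
    max_depth: float
    descent_end: float
    ascent_start: float

    def __post_init__(self) -> None:
        if not (self.start < self.descent_end <= self.ascent_start < self.end):
            raise ValueError(
                f"dive {self.dive_id}: phase boundaries out of order "
                f"({self.start}, {self.descent_end}, {self.ascent_start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def bottom_duration(self) -> float:
        return self.ascent_start - self.descent_end

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def zero_offset_correct(depth: DepthTrace, zoc_window: float = 600.0) -> DepthTrace:
    """Remove slow pressure-sensor drift so surface readings sit at 0 m.

    A centred rolling minimum over ``zoc_window`` seconds estimates the
    surface baseline (valid while the animal surfaces at least once per
    window); the baseline is subtracted and the result floored at 0.
    """
    if depth.n_samples == 0:
        return depth
    w = max(1, int(round(zoc_window * depth.sample_rate)))
    baseline = minimum_filter1d(depth.depth, size=w, mode="nearest")
    return DepthTrace(depth.start_time, depth.sample_rate, np.maximum(depth.depth - baseline, 0.0))


def split_phases(d: np.ndarray, t: np.ndarray, fraction: float = 0.1) -> tuple[float, float]:
    """Descent-end and ascent-start times for one dive's depth samples.

    Vertical speed is the first difference of depth; descent runs from the
    dive start until speed first falls below ``fraction`` of the dive's peak
    vertical speed, ascent symmetrically from the end, bottom is what
    remains.  A pure V-dive yields a zero-length bottom at the apex.
    """
    if len(d) < 2:
        return float(t[0]), float(t[0])
    v = np.gradient(d, t)
    peak = float(np.max(np.abs(v)))
    if peak <= 0:
        return float(t[0]), float(t[0])
    thr = fraction * peak
    below = np.flatnonzero(v < thr)
    descent_end_i = int(below[0]) if len(below) else len(d) - 1
    above = np.flatnonzero(v > -thr)
    ascent_start_i = int(above[-1]) if len(above) else 0
    if ascent_start_i < descent_end_i:
        apex = int(np.argmax(d))
        descent_end_i = ascent_start_i = apex
    return float(t[descent_end_i]), float(t[ascent_start_i])


def find_dives(depth: DepthTrace, params: DiveParams = DiveParams()) -> list[Dive]:
    """Extract dives from a zero-offset-corrected depth trace.

    A dive is a contiguous run of samples deeper than the surface-exclusion
    depth whose maximum exceeds ``min_dive_depth``; its start/end are the
    bracketing surface-exclusion crossings.  Returns dives in time order
    with phase boundaries attached.
    """
    d = depth.depth
    if len(d) == 0:
        return []
    t = depth.times()
    wet = d > params.surface_exclusion_depth
    # run-length segmentation of the wet mask
    edges = np.diff(wet.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if wet[0]:
        starts.insert(0, 0)
    if wet[-1]:
        ends.append(len(d))
    dives = []
    for i0, i1 in zip(starts, ends):
        seg = d[i0:i1]
        if seg.max() < params.min_dive_depth:
            continue
        de, asc = split_phases(seg, t[i0:i1], params.phase_speed_fraction)
        start, end = float(t[i0]), float(t[i1 - 1])
        de = min(max(de, start + 0.5 / depth.sample_rate), end)
        asc = min(max(asc, de), end - 0.5 / depth.sample_rate)
        dives.append(
            Dive(
                dive_id=len(dives),
                start=start,
                end=end,
                max_depth=float(seg.max()),
                descent_end=de,
                ascent_start=asc,
            )
        )
    return dives


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    """Dive table (one row per dive) for reporting and CSV export."""
    return pd.DataFrame(
        [
            {
                "dive_id": dv.dive_id,
                "start_s": dv.start,
                "end_s": dv.end,
                "max_depth_m": dv.max_depth,
                "descent_end_s": dv.descent_end,
                "ascent_start_s": dv.ascent_start,
                "bottom_duration_s": dv.bottom_duration,
            }
            for dv in dives
        ],
        columns=[
            "dive_id",
            "start_s",
            "end_s",
            "max_depth_m",
            "descent_end_s",
            "ascent_start_s",
            "bottom_duration_s",
        ],
    )
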