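"""Synthetic biologging deployments with known ground truth.

Generates per-animal deployments — 20 Hz tri-axial head acceleration,
1 Hz depth, and an annotation table of every injected event — with the
statistical structure of benthic-foraging fur seal data: trapezoidal dives
to 61-86 m, 1-7 attempted prey captures per dive (mean 2.6 +/- 1.6) placed
in the bottom phase, successful captures (93%) lasting 4.1 +/- 2.7 s with
1-8 handling sub-bursts versus single-burst unsuccessful attempts of
2.7 +/- 1.2 s, plus optional non-feeding head-movement distractors.

The acceleration signal is built so the detector's stages are each
exercised meaningfully: a slow orientation/gravity drift (removed by the
high-pass filter), a swimming-stroke oscillation below the filter cutoff,
APC bursts as Hanning-windowed sinusoid packets above the cutoff, white
sensor noise, and a hard clip at the logger's +/-3 g gain limit.

Determinism: each dive draws from its own child generator seeded
``(seed, 1000 + dive_index)`` in a fixed order (max depth, then prey
count, then per-event attributes), so per-dive draws can be re-derived
independently of signal synthesis; sensor noise comes from ``(seed, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import VideoEvent, write_events
from .signal_io import AccelTrace, DepthTrace, write_accel, write_depth

__all__ = [
    "SimConfig",
    "TruthRecord",
    "PackingError",
    "generate_deployment",
    "write_deployment",
    "read_truth",
    "truth_to_events",
    "burst_waveform",
    "stroke_waveform",
]

# fraction of burst energy injected on each axis relative to surge; heave is
# attenuated because head strikes are mostly fore-aft and lateral
_AXIS_SCALE = {"surge": 1.0, "sway": 0.9, "heave": 0.5}
_AXIS_OFFSET = {"surge": 0.05, "sway": 0.0, "heave": 0.9}  # static gravity component, g


class PackingError(ValueError):
    """The requested events/dives do not fit the requested duration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic deployment.

    ``duration`` may be None to size the record to exactly fit the dive
    schedule; an explicit duration too short for the schedule raises
    :class:`PackingError` rather than silently truncating.
    """

    seed: int = 0
    n_dives: int = 10
    duration: float | None = None
    sample_rate_accel: float = 20.0
    sample_rate_depth: float = 1.0
    clip_limit: float = 3.0
    max_depth_range: tuple[float, float] = (61.0, 86.0)
    prey_per_dive_mean: float = 2.6
    prey_per_dive_sd: float = 1.6
    prey_per_dive_range: tuple[int, int] = (1, 7)
    apc_burst_freq: float = 6.0
    apc_duration_mean: float = 4.1
    apc_duration_sd: float = 2.7
    apc_duration_mean_unsuccessful: float = 2.7
    apc_duration_sd_unsuccessful: float = 1.2
    apc_amplitude: float = 1.5
    baseline_stroke_freq: float = 1.2
    baseline_stroke_amplitude: float = 0.25
    orientation_drift_amplitude: float = 0.4
    orientation_drift_freq: float = 0.01
    noise_sd: float = 0.05
    distractor_rate: float = 0.0
    distractor_amplitude: float | None = None
    success_prob: float = 0.93
    prey_type_probs: dict = field(
        default_factory=lambda: {"fish": 0.80, "cephalopod": 0.03, "stingray": 0.02, "unknown": 0.15}
    )
    highpass_cutoff: float = 3.0  # detector cutoff the frequencies must straddle
    descent_rate: float = 1.5  # m/s, also ascent
    surface_interval: float = 60.0  # s between dives
    event_gap_range: tuple[float, float] = (25.0, 60.0)  # s between event burst trains
    bottom_margin: float = 3.0  # s of quiet bottom before/after the event chain
    annotation_pad: float = 1.0  # s of chase lead-in / handling tail around the bursts

    def __post_init__(self) -> None:
        if self.apc_burst_freq <= self.highpass_cutoff:
            raise ValueError("apc_burst_freq must exceed the detector high-pass cutoff")
        if self.baseline_stroke_freq >= self.highpass_cutoff:
            raise ValueError("baseline_stroke_freq must sit below the high-pass cutoff")
        if self.apc_burst_freq >= self.sample_rate_accel / 2:
            raise ValueError("apc_burst_freq must be below the accelerometer Nyquist rate")
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must lie in [0, 1]")
        if self.n_dives < 0:
            raise ValueError("n_dives must be non-negative")
        lo, hi = self.prey_per_dive_range
        if not (1 <= lo <= hi):
            raise ValueError("prey_per_dive_range must satisfy 1 <= lo <= hi")
        total = sum(self.prey_type_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"prey_type_probs must sum to 1, got {total}")


@dataclass(frozen=True)
class TruthRecord:
    """One injected event: an APC (with its annotation window) or a distractor."""

    dive_id: int
    start: float
    end: float
    category: str  # annotation category, or "distractor"
    prey_type: str
    success: bool

    @property
    def is_apc(self) -> bool:
        return self.category != "distractor"


TRUTH_COLUMNS = ["dive_id", "start_s", "end_s", "category", "prey_type", "success"]


def burst_waveform(duration: float, carrier_hz: float, amplitude: float, sample_rate: float) -> np.ndarray:
    """Hanning-enveloped sinusoid packet modelling one head-movement burst."""
    n = max(int(round(duration * sample_rate)), 1)
    tt = np.arange(n) / sample_rate
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * carrier_hz * tt)


def stroke_waveform(t: np.ndarray, freq: float, amplitude: float, phase: float = 0.0) -> np.ndarray:
    """Steady swimming-stroke oscillation (below the detector cutoff)."""
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def _dive_rng(seed: int, dive_index: int) -> np.random.Generator:
    return np.random.default_rng((seed, 1000 + dive_index))


@dataclass
class _Item:
    """Internal: one scheduled burst train (APC or distractor) within a dive."""

    kind: str  # "apc" or "distractor"
    duration: float
    amplitude: float
    n_packets: int
    success: bool = False
    prey_type: str = "unknown"
    start: float = 0.0  # window start, absolute seconds; filled during layout


def _draw_dive_items(cfg: SimConfig, rng: np.random.Generator) -> tuple[float, list[_Item], list[float]]:
    """Per-dive draws in the documented order; returns (max_depth, items, gaps)."""
    max_depth = rng.uniform(*cfg.max_depth_range)
    lo, hi = cfg.prey_per_dive_range
    n_prey = int(np.clip(np.round(rng.normal(cfg.prey_per_dive_mean, cfg.prey_per_dive_sd)), lo, hi))
    items: list[_Item] = []
    prey_names = list(cfg.prey_type_probs)
    prey_p = np.array([cfg.prey_type_probs[k] for k in prey_names])
    for _ in range(n_prey):
        success = bool(rng.random() < cfg.success_prob)
        if success:
            dur = float(np.clip(rng.normal(cfg.apc_duration_mean, cfg.apc_duration_sd), 1.0, 9.0))
            n_packets = int(max(1, min(8, round(dur / 1.5))))
        else:
            dur = float(
                np.clip(
                    rng.normal(cfg.apc_duration_mean_unsuccessful, cfg.apc_duration_sd_unsuccessful),
                    1.0,
                    6.0,
                )
            )
            n_packets = 1
        prey = str(rng.choice(prey_names, p=prey_p))
        amp = cfg.apc_amplitude * rng.uniform(0.9, 1.1)
        items.append(_Item("apc", dur, amp, n_packets, success, prey))
    n_distr = int(rng.poisson(cfg.distractor_rate))
    d_amp = cfg.distractor_amplitude if cfg.distractor_amplitude is not None else cfg.apc_amplitude
    for _ in range(n_distr):
        dur = float(rng.uniform(1.0, 2.0))
        items.append(_Item("distractor", dur, d_amp * rng.uniform(0.9, 1.1), 1))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    gaps = [float(rng.uniform(*cfg.event_gap_range)) for _ in range(max(len(items) - 1, 0))]
    return max_depth, items, gaps


def _category(item: _Item) -> str:
    if item.kind == "distractor":
        return "distractor"
    if not item.success:
        return "chase_missed"
    return "chase_capture_handling" if item.n_packets >= 2 else "chase_capture_no_handling"


def generate_deployment(cfg: SimConfig) -> tuple[AccelTrace, DepthTrace, list[TruthRecord]]:
    """Build one deployment: acceleration, depth and the truth table.

    Identical configs (including seed) give byte-identical output.  Dives
    are trapezoidal (constant-rate descent/ascent, flat bottom sized to the
    event chain); the truth table lists every injected APC with its
    annotation window — the burst train padded by ``annotation_pad`` of
    chase lead-in and handling tail, so detector peaks smeared outward by
    the moving-variance window still fall inside it — and every distractor.
    """
    fs = cfg.sample_rate_accel
    # --- schedule dives
    dive_specs = []  # (start, descent_dur, bottom_dur, ascent_dur, max_depth, items)
    cursor = cfg.surface_interval
    truth: list[TruthRecord] = []
    for i in range(cfg.n_dives):
        rng = _dive_rng(cfg.seed, i)
        max_depth, items, gaps = _draw_dive_items(cfg, rng)
        descent = max_depth / cfg.descent_rate
        bottom_start = cursor + descent
        t = bottom_start + cfg.bottom_margin
        for j, item in enumerate(items):
            item.start = t
            t += item.duration
            if j < len(gaps):
                t += gaps[j]
        bottom = (t - bottom_start) + cfg.bottom_margin
        bottom = max(bottom, 2 * cfg.bottom_margin)
        dive_specs.append((cursor, descent, bottom, descent, max_depth, items))
        for item in items:
            truth.append(
                TruthRecord(
                    dive_id=i,
                    start=item.start - cfg.annotation_pad,
                    end=item.start + item.duration + cfg.annotation_pad,
                    category=_category(item),
                    prey_type=item.prey_type,
                    success=item.success,
                )
            )
        cursor += descent + bottom + descent + cfg.surface_interval

    required = cursor if cfg.n_dives else cfg.surface_interval
    if cfg.duration is None:
        duration = required
    else:
        if cfg.duration < required - 1e-9:
            raise PackingError(
                f"duration {cfg.duration:.1f} s cannot accommodate {cfg.n_dives} dives "
                f"with their events and surface intervals (need {required:.1f} s)"
            )
        duration = cfg.duration

    # --- depth profile (1 Hz, piecewise linear through the dive corners)
    knots_t, knots_d = [0.0], [0.0]
    for start, descent, bottom, ascent, max_depth, _ in dive_specs:
        knots_t += [start, start + descent, start + descent + bottom, start + descent + bottom + ascent]
        knots_d += [0.0, max_depth, max_depth, 0.0]
    knots_t.append(duration)
    knots_d.append(0.0)
    n_depth = int(round(duration * cfg.sample_rate_depth)) + 1
    t_depth = np.arange(n_depth) / cfg.sample_rate_depth
    depth = np.interp(t_depth, knots_t, knots_d)
    depth_trace = DepthTrace(start_time=0.0, sample_rate=cfg.sample_rate_depth, depth=depth)

    # --- acceleration (20 Hz)
    n_acc = int(round(duration * fs))
    t_acc = np.arange(n_acc) / fs
    rng_noise = np.random.default_rng((cfg.seed, 1))
    axes = {}
    for k, name in enumerate(("surge", "sway", "heave")):
        sig = np.full(n_acc, _AXIS_OFFSET[name])
        sig += cfg.orientation_drift_amplitude * np.sin(
            2 * np.pi * cfg.orientation_drift_freq * t_acc + 0.7 * k
        )
        sig += stroke_waveform(t_acc, cfg.baseline_stroke_freq, cfg.baseline_stroke_amplitude, 1.3 * k)
        sig += rng_noise.normal(0.0, cfg.noise_sd, n_acc)
        axes[name] = sig
    for _, _, _, _, _, items in dive_specs:
        for item in items:
            slot = item.duration / item.n_packets
            width = min(1.8, slot)
            for p in range(item.n_packets):
                centre = item.start + (p + 0.5) * slot
                packet = burst_waveform(width, cfg.apc_burst_freq, item.amplitude, fs)
                i0 = int(round((centre - width / 2) * fs))
                i1 = min(i0 + len(packet), n_acc)
                if i0 >= n_acc:
                    continue
                for name in axes:
                    axes[name][i0:i1] += _AXIS_SCALE[name] * packet[: i1 - i0]
    for name in axes:
        np.clip(axes[name], -cfg.clip_limit, cfg.clip_limit, out=axes[name])

    accel = AccelTrace(
        start_time=0.0,
        sample_rate=fs,
        surge=axes["surge"],
        sway=axes["sway"],
        heave=axes["heave"],
        clip_limit=cfg.clip_limit,
    )
    truth.sort(key=lambda r: r.start)
    return accel, depth_trace, truth


def truth_to_events(truth: list[TruthRecord]) -> list[VideoEvent]:
    """Video-visible annotation events (distractors are not on video)."""
    events = []
    for r in truth:
        if not r.is_apc:
            continue
        location = "benthic" if r.prey_type in ("fish", "unknown") else "ascent_surface"
        events.append(
            VideoEvent(
                dive_id=r.dive_id,
                start=r.start,
                end=r.end,
                category=r.category,
                prey_type=r.prey_type,
                location=location,
            )
        )
    return events


def write_deployment(
    accel: AccelTrace, depth: DepthTrace, truth: list[TruthRecord], directory
) -> dict[str, Path]:
    """Write accel.csv / depth.csv / events.csv / truth.csv into ``directory``.

    ``events.csv`` is the video-annotation view (distractors omitted,
    readable by :func:`apcdetect.annotations.read_events`); ``truth.csv``
    is the full generator record including distractors.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "accel": directory / "accel.csv",
        "depth": directory / "depth.csv",
        "events": directory / "events.csv",
        "truth": directory / "truth.csv",
    }
    write_accel(accel, paths["accel"])
    write_depth(depth, paths["depth"])
    write_events(truth_to_events(truth), paths["events"])
    frame = pd.DataFrame(
        [
            {
                "dive_id": r.dive_id,
                "start_s": r.start,
                "end_s": r.end,
                "category": r.category,
                "prey_type": r.prey_type,
                "success": r.success,
            }
            for r in truth
        ],
        columns=TRUTH_COLUMNS,
    )
    frame.to_csv(paths["truth"], index=False, float_format="%.17g")
    return paths


def read_truth(path) -> list[TruthRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return [
        TruthRecord(
            dive_id=int(r["dive_id"]),
            start=float(r["start_s"]),
            end=float(r["end_s"]),
            category=str(r["category"]),
            prey_type=str(r["prey_type"]),
            success=bool(r["success"]),
        )
        for _, r in frame.iterrows()
    ]
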