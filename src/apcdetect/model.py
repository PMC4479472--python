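"""Model/results interface for accelerometer prey-capture validation.

:class:`CaptureValidation` is built from per-animal deployments (aligned
acceleration + depth + video annotations); :meth:`CaptureValidation.fit`
runs the whole validation study — dive segmentation, a seeded 50/50
dive-level holdout per animal, a detector parameter grid search on the
training dives, the animal-specific/generic parameter choice, and the
testing-subset evaluation — and returns a
:class:`CaptureValidationResults` carrying per-animal metrics, their
across-animal means and SDs, paired generic-vs-specific differences, the
dive-level foraging-dive error, and a ``summary()`` table laid out the way
such validation studies report error metrics (axis x parameter set x
detection / FP rate / precision, mean +/- SD across animals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotations import VideoEvent, events_by_dive, read_events
from .detector import DetectorParams, build_variance_cache, detect_from_cache
from .dives import Dive, DiveParams, find_dives, zero_offset_correct
from .matching import ConfusionCounts
from .metrics import (
    AnimalSummary,
    ErrorMetrics,
    aggregate_per_animal,
    classify_foraging_dives,
    compute_metrics,
    foraging_dive_error,
)
from .optimize import (
    GridResult,
    SplitAssignment,
    evaluate_params,
    generic_params,
    grid_search_animal,
    random_split,
    select_animal_specific,
)
from .signal_io import AccelTrace, DepthTrace, align_streams, read_accel, read_depth, upsample_depth
from .synthetic import SimConfig, generate_deployment, truth_to_events

__all__ = ["Deployment", "CaptureValidation", "CaptureValidationResults"]


@dataclass
class Deployment:
    """One animal's aligned sensor record plus its video annotations."""

    animal_id: str
    accel: AccelTrace
    depth: DepthTrace  # native (typically 1 Hz) depth record
    events: list[VideoEvent]
    dives: list[Dive] = field(default_factory=list, repr=False)
    _depth_hi: DepthTrace | None = field(default=None, repr=False)
    _events_per_dive: dict[int, list[VideoEvent]] | None = field(default=None, repr=False)

    @classmethod
    def from_files(cls, animal_id: str, accel_path, depth_path, events_path) -> "Deployment":
        return cls(
            animal_id=animal_id,
            accel=read_accel(accel_path),
            depth=read_depth(depth_path),
            events=read_events(events_path),
        )

    @classmethod
    def from_simulation(cls, animal_id: str, config: SimConfig) -> "Deployment":
        accel, depth, truth = generate_deployment(config)
        return cls(animal_id=animal_id, accel=accel, depth=depth, events=truth_to_events(truth))

    def prepare(self, dive_params: DiveParams = DiveParams()) -> "Deployment":
        """Upsample + zero-offset-correct depth, align streams, find dives."""
        hi = upsample_depth(self.depth, self.accel.sample_rate)
        hi = zero_offset_correct(hi, dive_params.zoc_window)
        accel, hi = align_streams(self.accel, hi)
        self.accel = accel
        self._depth_hi = hi
        self.dives = find_dives(hi, dive_params)
        self._events_per_dive = events_by_dive(self.dives, self.events)
        return self

    @property
    def depth_hi(self) -> DepthTrace:
        if self._depth_hi is None:
            raise RuntimeError("call prepare() first")
        return self._depth_hi

    @property
    def events_per_dive(self) -> dict[int, list[VideoEvent]]:
        if self._events_per_dive is None:
            raise RuntimeError("call prepare() first")
        return self._events_per_dive


class CaptureValidation:
    """Validation study of the variance-peak APC detector on a cohort.

    Parameters
    ----------
    deployments
        One :class:`Deployment` per animal.
    axes
        Acceleration axes to analyse (any of surge/sway/heave).
    dive_params, detector
        Segmentation thresholds and fixed detector settings (filter cutoff,
        variance window); the variance threshold and minimum interval in
        ``detector`` are overridden by the grid search.
    """

    def __init__(
        self,
        deployments: Sequence[Deployment],
        axes: Sequence[str] = ("surge", "sway", "heave"),
        dive_params: DiveParams = DiveParams(),
        detector: DetectorParams = DetectorParams(),
    ) -> None:
        if not deployments:
            raise ValueError("need at least one deployment")
        self.deployments = list(deployments)
        self.axes = tuple(axes)
        self.dive_params = dive_params
        self.detector = detector
        for dep in self.deployments:
            if not dep.dives:
                dep.prepare(dive_params)

    @classmethod
    def from_simulation(
        cls,
        n_animals: int = 4,
        seed: int = 0,
        axes: Sequence[str] = ("surge",),
        config: SimConfig | None = None,
        **config_overrides,
    ) -> "CaptureValidation":
        """Simulate a cohort; animal ``k`` uses seed ``seed * 1000 + k``."""
        base = config or SimConfig(**config_overrides)
        deployments = []
        for k in range(n_animals):
            cfg = SimConfig(**{**base.__dict__, "seed": seed * 1000 + k})
            deployments.append(Deployment.from_simulation(f"A{k + 1}", cfg))
        return cls(deployments, axes=axes)

    def fit(
        self,
        seed: int = 0,
        proportion: float = 0.5,
        tie_window: float = 2.0,
        thresholds: Sequence[float] | None = None,
        intervals: Sequence[float] | None = None,
    ) -> "CaptureValidationResults":
        """Run split -> grid search -> selection -> testing evaluation."""
        splits: dict[str, SplitAssignment] = {}
        for k, dep in enumerate(self.deployments):
            splits[dep.animal_id] = random_split(
                [d.dive_id for d in dep.dives], proportion, seed * 1000 + k
            )

        grid_results: list[GridResult] = []
        chosen: dict[str, dict[str, DetectorParams]] = {ax: {} for ax in self.axes}
        testing_counts: dict[str, dict[str, dict[str, ConfusionCounts]]] = {
            ax: {"generic": {}, "animal_specific": {}} for ax in self.axes
        }
        caches: dict[str, dict[str, list]] = {}
        for ax in self.axes:
            caches[ax] = {}
            for dep in self.deployments:
                cache = build_variance_cache(
                    dep.accel,
                    dep.depth_hi,
                    dep.dives,
                    self.detector.with_(axis=ax),
                    self.dive_params.surface_exclusion_depth,
                )
                caches[ax][dep.animal_id] = cache
                split = splits[dep.animal_id]
                results = grid_search_animal(
                    dep.animal_id,
                    cache,
                    dep.events_per_dive,
                    split,
                    ax,
                    thresholds,
                    intervals,
                    self.detector,
                )
                grid_results.extend(results)
                pick = select_animal_specific(results, tie_window)
                specific = self.detector.with_(
                    axis=ax,
                    variance_threshold=pick.variance_threshold,
                    min_interval=pick.min_interval,
                )
                chosen[ax][dep.animal_id] = specific
                for kind, params in (
                    ("generic", generic_params(ax, self.detector)),
                    ("animal_specific", specific),
                ):
                    testing_counts[ax][kind][dep.animal_id] = evaluate_params(
                        cache, dep.events_per_dive, split.testing_ids, params
                    )

        # dive-level foraging classification: testing subset, generic params,
        # on the first analysed axis (surge when present)
        foraging = {}
        f_ax = "surge" if "surge" in self.axes else self.axes[0]
        frames = []
        for dep in self.deployments:
            split = splits[dep.animal_id]
            wanted = set(split.testing_ids)
            detections = detect_from_cache(
                [dv for dv in caches[f_ax][dep.animal_id] if dv.dive_id in wanted],
                generic_params(f_ax, self.detector),
            )
            frame = classify_foraging_dives(
                detections,
                dep.events_per_dive,
                [d for d in dep.dives if d.dive_id in wanted],
            )
            frame.insert(0, "animal", dep.animal_id)
            frames.append(frame)
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        n_video = int(table["video_foraging"].sum()) if len(table) else 0
        n_accel = int(table["accel_foraging"].sum()) if len(table) else 0
        foraging = {
            "axis": f_ax,
            "table": table,
            "n_video_foraging": n_video,
            "n_accel_foraging": n_accel,
            "underestimate_pct": foraging_dive_error(n_video, n_accel) if n_video else None,
        }

        return CaptureValidationResults(
            model=self,
            splits=splits,
            grid_results=grid_results,
            animal_params=chosen,
            testing_counts=testing_counts,
            foraging=foraging,
            fit_seed=seed,
            tie_window=tie_window,
        )


@dataclass
class CaptureValidationResults:
    """Fitted validation study: selected parameters and testing-subset errors."""

    model: CaptureValidation
    splits: Mapping[str, SplitAssignment]
    grid_results: list[GridResult]
    animal_params: Mapping[str, Mapping[str, DetectorParams]]  # axis -> animal -> params
    testing_counts: Mapping[str, Mapping[str, Mapping[str, ConfusionCounts]]]
    foraging: dict
    fit_seed: int
    tie_window: float

    def testing_metrics(self, axis: str, kind: str) -> dict[str, ErrorMetrics]:
        """Per-animal testing-subset metrics for ``kind`` in {generic, animal_specific}."""
        return {a: compute_metrics(c) for a, c in self.testing_counts[axis][kind].items()}

    def aggregate(self, axis: str, kind: str) -> dict[str, AnimalSummary]:
        return aggregate_per_animal(self.testing_metrics(axis, kind))

    def total_apc(self, axis: str, kind: str) -> int:
        return sum(c.n_detections for c in self.testing_counts[axis][kind].values())

    def paired_differences(self, axis: str) -> pd.DataFrame:
        """Per-animal generic-minus-specific metric differences (testing subset)."""
        gen = self.testing_metrics(axis, "generic")
        spec = self.testing_metrics(axis, "animal_specific")
        rows = []
        for animal in gen:
            g, s = gen[animal], spec[animal]
            rows.append(
                {
                    "animal": animal,
                    "detection_diff_pct": None
                    if g.detection is None or s.detection is None
                    else g.detection - s.detection,
                    "fp_rate_diff_pct": None
                    if g.fp_rate is None or s.fp_rate is None
                    else g.fp_rate - s.fp_rate,
                }
            )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for ax in self.model.axes:
            for kind, label in (("generic", "Generic"), ("animal_specific", "Animal-specific")):
                agg = self.aggregate(ax, kind)
                row = {"axis": ax, "parameters": label, "total_apc": self.total_apc(ax, kind)}
                for name in ("detection", "fp_rate", "precision"):
                    summ = agg.get(name)
                    row[f"{name}_mean_pct"] = None if summ is None else round(summ.mean, 1)
                    row[f"{name}_sd_pct"] = None if summ is None else round(summ.sd, 1)
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report: error metrics averaged over animals, per axis."""
        lines = [
            "Accelerometer APC validation — testing subset, mean (SD) across animals",
            f"animals: {len(self.model.deployments)}; axes: {', '.join(self.model.axes)}; "
            f"split seed {self.fit_seed}; tie window {self.tie_window:g}%",
            "",
            f"{'Axis':8s}{'Parameters':18s}{'Detection %':>14s}{'FP rate %':>14s}{'Precision %':>14s}{'Total APC':>11s}",
        ]
        for _, r in self.summary_frame().iterrows():
            def cell(m, s):
                return "--" if r[m] is None else f"{r[m]:.1f} ({r[s]:.1f})"

            lines.append(
                f"{r['axis']:8s}{r['parameters']:18s}"
                f"{cell('detection_mean_pct', 'detection_sd_pct'):>14s}"
                f"{cell('fp_rate_mean_pct', 'fp_rate_sd_pct'):>14s}"
                f"{cell('precision_mean_pct', 'precision_sd_pct'):>14s}"
                f"{r['total_apc']:>11d}"
            )
        lines.append("")
        for ax in self.model.axes:
            picks = ", ".join(
                f"{a}: {p.variance_threshold:g}/{p.min_interval:g}s"
                for a, p in sorted(self.animal_params[ax].items())
            )
            lines.append(f"animal-specific parameters [{ax}]: {picks}")
        f = self.foraging
        if f.get("underestimate_pct") is not None:
            lines.append(
                f"foraging dives ({f['axis']}, generic): video {f['n_video_foraging']}, "
                f"accelerometer {f['n_accel_foraging']} -> "
                f"underestimate {f['underestimate_pct']:.1f}%"
            )
        return "\n".join(lines)
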