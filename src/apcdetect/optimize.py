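"""Holdout parameter optimisation of the APC detector.

Each animal's annotated dives are partitioned once into ~50% training and
~50% testing subsets.  Every (variance threshold, minimum interval) grid
point is evaluated on the training dives only; the animal-specific choice
maximises detection, with combinations within a 2-percentage-point tie
window resolved by highest precision (residual ties: lowest threshold,
then shortest interval — the most sensitive setting).  The generic
parameters shared by all animals are 0.1 g^2 and 5 s.  Testing dives never
touch selection: every metric row carries a subset provenance tag and the
selector refuses rows not tagged "training".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import VideoEvent
from .detector import (
    GENERIC_MIN_INTERVAL,
    GENERIC_THRESHOLD,
    HEAVE_THRESHOLDS,
    MIN_INTERVALS,
    SURGE_SWAY_THRESHOLDS,
    DetectorParams,
    DiveVariance,
    detect_from_cache,
)
from .matching import ConfusionCounts, match_dive, pool_counts
from .metrics import ErrorMetrics, compute_metrics

__all__ = [
    "SplitAssignment",
    "GridResult",
    "random_split",
    "split_summary",
    "default_grid",
    "generic_params",
    "grid_search_animal",
    "select_animal_specific",
    "evaluate_params",
    "grid_results_to_frame",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Dive-level training/testing partition for one animal."""

    assignment: Mapping[int, str]  # dive_id -> "training" | "testing"
    seed: int
    proportion: float = 0.5

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values()} - {"training", "testing"}
        if bad:
            raise ValueError(f"invalid subset labels {bad}")

    @property
    def training_ids(self) -> list[int]:
        return sorted(k for k, v in self.assignment.items() if v == "training")

    @property
    def testing_ids(self) -> list[int]:
        return sorted(k for k, v in self.assignment.items() if v == "testing")

    @property
    def training_fraction(self) -> float:
        return len(self.training_ids) / len(self.assignment)


def random_split(dive_ids: Sequence[int], proportion: float = 0.5, seed: int = 0) -> SplitAssignment:
    """Seeded random dive-level partition into training/testing subsets.

    A permutation split: dives are shuffled and the first
    ``round(n * proportion)`` assigned to training, so the realised
    proportion sits as close to the target as an integer count allows
    (48.6-51.4% for cohorts of a few dozen dives at 50%).  Each dive is
    used exactly once.
    """
    dive_ids = list(dive_ids)
    if len(dive_ids) < 2:
        raise ValueError("need at least 2 dives to split")
    if not 0 < proportion < 1:
        raise ValueError("proportion must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dive_ids))
    n_train = int(round(len(dive_ids) * proportion))
    n_train = min(max(n_train, 1), len(dive_ids) - 1)
    training = {dive_ids[i] for i in order[:n_train]}
    assignment = {d: ("training" if d in training else "testing") for d in dive_ids}
    return SplitAssignment(assignment=assignment, seed=seed, proportion=proportion)


def split_summary(split: SplitAssignment) -> dict:
    return {
        "n_dives": len(split.assignment),
        "n_training": len(split.training_ids),
        "n_testing": len(split.testing_ids),
        "training_pct": 100.0 * split.training_fraction,
    }


def default_grid(axis: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(thresholds, intervals) for an axis; heave drops the 0.8 threshold."""
    thresholds = HEAVE_THRESHOLDS if axis == "heave" else SURGE_SWAY_THRESHOLDS
    return thresholds, MIN_INTERVALS


def generic_params(axis: str, base: DetectorParams = DetectorParams()) -> DetectorParams:
    """The shared one-size-fits-all setting: 0.1 g^2 threshold, 5 s interval."""
    return base.with_(axis=axis, variance_threshold=GENERIC_THRESHOLD, min_interval=GENERIC_MIN_INTERVAL)


@dataclass(frozen=True)
class GridResult:
    """Metrics of one grid point for one animal on one subset."""

    animal: str
    axis: str
    variance_threshold: float
    min_interval: float
    counts: ConfusionCounts
    metrics: ErrorMetrics
    subset: str = "training"  # provenance tag; selection accepts "training" only


def evaluate_params(
    cache: list[DiveVariance],
    events_per_dive: Mapping[int, list[VideoEvent]],
    dive_ids: Sequence[int],
    params: DetectorParams,
) -> ConfusionCounts:
    """Detect on the cached variance of ``dive_ids`` and pool match counts."""
    wanted = set(dive_ids)
    sub_cache = [dv for dv in cache if dv.dive_id in wanted]
    detections = detect_from_cache(sub_cache, params)
    by_dive: dict[int, list] = {d: [] for d in wanted}
    for det in detections:
        by_dive[det.dive_id].append(det)
    counts = []
    for d in sorted(wanted):
        _, c = match_dive(by_dive[d], events_per_dive.get(d, []), d)
        counts.append(c)
    return pool_counts(counts)


def grid_search_animal(
    animal: str,
    cache: list[DiveVariance],
    events_per_dive: Mapping[int, list[VideoEvent]],
    split: SplitAssignment,
    axis: str,
    thresholds: Sequence[float] | None = None,
    intervals: Sequence[float] | None = None,
    base: DetectorParams = DetectorParams(),
    subset: str = "training",
) -> list[GridResult]:
    """Evaluate the full parameter grid for one animal on one subset."""
    default_thr, default_int = default_grid(axis)
    thresholds = tuple(thresholds) if thresholds is not None else default_thr
    intervals = tuple(intervals) if intervals is not None else default_int
    dive_ids = split.training_ids if subset == "training" else split.testing_ids
    results = []
    for thr in thresholds:
        for itv in intervals:
            params = base.with_(axis=axis, variance_threshold=thr, min_interval=itv)
            counts = evaluate_params(cache, events_per_dive, dive_ids, params)
            results.append(
                GridResult(
                    animal=animal,
                    axis=axis,
                    variance_threshold=thr,
                    min_interval=itv,
                    counts=counts,
                    metrics=compute_metrics(counts),
                    subset=subset,
                )
            )
    return results


def select_animal_specific(
    results: Sequence[GridResult],
    tie_window: float = 2.0,
) -> GridResult:
    """Pick one animal's parameters from its training-subset grid results.

    Maximise detection; results within ``tie_window`` percentage points of
    the best detection are tied and resolved by highest precision; residual
    ties go to the lowest variance threshold, then the shortest interval.
    Raises if any result carries a non-training provenance tag or if no
    result has a defined detection rate.
    """
    if not results:
        raise ValueError("no grid results to select from")
    tainted = [r for r in results if r.subset != "training"]
    if tainted:
        raise ValueError(
            f"parameter selection must only see training-subset results; got {tainted[0].subset!r}"
        )
    defined = [r for r in results if r.metrics.detection is not None]
    if not defined:
        raise ValueError("no grid result has a defined detection rate")
    best = max(r.metrics.detection for r in defined)
    candidates = [r for r in defined if r.metrics.detection >= best - tie_window]

    def key(r: GridResult):
        precision = r.metrics.precision if r.metrics.precision is not None else -1.0
        return (-precision, r.variance_threshold, r.min_interval)

    return min(candidates, key=key)


def grid_results_to_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal": r.animal,
                "axis": r.axis,
                "subset": r.subset,
                "variance_threshold": r.variance_threshold,
                "min_interval_s": r.min_interval,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
                "detection_pct": r.metrics.detection,
                "fp_rate_pct": r.metrics.fp_rate,
                "precision_pct": r.metrics.precision,
            }
            for r in results
        ]
    )
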