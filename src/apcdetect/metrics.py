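"""Error metrics from confusion counts; per-animal averaging; foraging dives.

Definitions (percent):

* detection rate (sensitivity/recall) = 100 * TP / (TP + FN)
* precision = 100 * TP / (TP + FP)
* FP rate = 100 * FP / (TP + FP) = 100 - precision

The FP-rate definition is the share of *detections* that are spurious (the
complement of precision), not the classical FP/(FP+TN): dive-level true
negatives are poorly defined for a free-ranging forager, so accuracy and
specificity are deliberately not computed.  Per-animal averaging is
counts-first — counts are pooled over an animal's dives, one metric per
animal, then an unweighted mean +/- SD across animals so every animal is
one data point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .annotations import VideoEvent, apc_events
from .detector import DetectedAPC
from .dives import Dive
from .matching import ConfusionCounts

__all__ = [
    "ErrorMetrics",
    "compute_metrics",
    "precision_from_fp_rate",
    "AnimalSummary",
    "aggregate_per_animal",
    "classify_foraging_dives",
    "foraging_dive_error",
]


@dataclass(frozen=True)
class ErrorMetrics:
    """Detection / FP rate / precision in percent; None when undefined.

    A denominator of zero yields None plus a reason string, never a silent
    0: an animal with no video APC events has no measurable detection rate.
    """

    detection: float | None
    fp_rate: float | None
    precision: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.detection is not None and self.precision is not None


def compute_metrics(counts: ConfusionCounts) -> ErrorMetrics:
    reasons = []
    if counts.tp + counts.fn > 0:
        detection = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        detection = None
        reasons.append("no video APC events (TP+FN=0)")
    if counts.tp + counts.fp > 0:
        precision = 100.0 * counts.tp / (counts.tp + counts.fp)
        fp_rate = 100.0 - precision  # exact complement by construction
    else:
        precision = fp_rate = None
        reasons.append("no detections (TP+FP=0)")
    return ErrorMetrics(detection, fp_rate, precision, "; ".join(reasons) or None)


def precision_from_fp_rate(fp_rate: float) -> float:
    """Precision implied by an FP rate via the identity FP rate + precision = 100."""
    return 100.0 - fp_rate


@dataclass(frozen=True)
class AnimalSummary:
    """Unweighted mean +/- SD of one metric across animals."""

    mean: float
    sd: float
    n: int
    n_undefined: int = 0


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate_per_animal(per_animal: Mapping[str, ErrorMetrics]) -> dict[str, AnimalSummary]:
    """Across-animal mean +/- SD for each metric (each animal one point).

    Animals whose metric is undefined are excluded from that metric's
    average and counted in ``n_undefined``; a single defined animal reports
    SD 0 with n = 1.  Raises if no animal has any defined metric.
    """
    out: dict[str, AnimalSummary] = {}
    for name in ("detection", "fp_rate", "precision"):
        vals = [getattr(m, name) for m in per_animal.values()]
        defined = [v for v in vals if v is not None]
        if defined:
            mean, sd = _mean_sd(defined)
            out[name] = AnimalSummary(mean, sd, len(defined), len(vals) - len(defined))
    if not out:
        raise ValueError("no animal has defined metrics to aggregate")
    return out


# ---------------------------------------------------------------------------
# dive-level foraging classification


def classify_foraging_dives(
    detections: list[DetectedAPC],
    events_per_dive: Mapping[int, list[VideoEvent]],
    dives: list[Dive],
) -> pd.DataFrame:
    """Per-dive foraging status from video and from the accelerometer.

    A foraging dive holds at least one APC — successful or not — on the
    respective source; abandoned chases do not count on video.
    """
    det_dives = {d.dive_id for d in detections}
    rows = []
    for dive in dives:
        video = len(apc_events(events_per_dive.get(dive.dive_id, []))) > 0
        accel = dive.dive_id in det_dives
        rows.append(
            {"dive_id": dive.dive_id, "video_foraging": video, "accel_foraging": accel}
        )
    return pd.DataFrame(rows, columns=["dive_id", "video_foraging", "accel_foraging"])


def foraging_dive_error(n_video_foraging: int, n_accel_foraging: int) -> float:
    """Percent under- (positive) or over- (negative) estimate of foraging dives.

    100 * (video - accelerometer) / video; undefined (raises) when video
    found no foraging dives.
    """
    if n_video_foraging == 0:
        raise ValueError("foraging-dive error undefined: video found no foraging dives")
    return 100.0 * (n_video_foraging - n_accel_foraging) / n_video_foraging
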