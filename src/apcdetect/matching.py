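"""Matching detector APCs to video events; confusion accounting.

Per dive, a detection matches a video event when the time of its first
variance peak falls inside the event's annotated window.  The earliest
matching detection per event is the true positive; any further detections
matched to the same event are "multiple-match" false positives (the
detector over-counted one capture).  Detections covered by no event window
are false positives outright; events no detection reached are false
negatives.  A dive empty on both sides contributes exactly one true
negative — TN is strictly dive-level, never per event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotations import VideoEvent, apc_events
from .detector import DetectedAPC

__all__ = ["ConfusionCounts", "MatchRecord", "match_dive", "pool_counts", "records_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies; additive over dives."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def n_detections(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MatchRecord:
    """Outcome of one detection or one unmatched event.

    ``label`` is TP / FP_outside / FP_multiple for detections, FN for an
    event no detection reached, TN for an empty dive.
    """

    dive_id: int
    label: str
    detection_time: float | None = None
    event_start: float | None = None


def _assign_event(det: DetectedAPC, events: list[VideoEvent]) -> VideoEvent | None:
    """Event whose window contains the detection's first-peak time.

    Overlapping windows are disambiguated deterministically: the event whose
    start lies nearest the detection time wins, ties to the earlier event.
    """
    containing = [e for e in events if e.contains(det.t_first_peak)]
    if not containing:
        return None
    if len(containing) > 1:
        logger.info(
            "detection at %.1fs inside %d overlapping event windows (dive %d); "
            "assigned to nearest event start",
            det.t_first_peak,
            len(containing),
            det.dive_id,
        )
    return min(containing, key=lambda e: (abs(det.t_first_peak - e.start), e.start))


def match_dive(
    detections: list[DetectedAPC],
    events: list[VideoEvent],
    dive_id: int,
) -> tuple[list[MatchRecord], ConfusionCounts]:
    """Match one dive's detections against its video APC events.

    Excluded-category events (abandoned chases) are filtered out before
    matching.  Invariants: TP + FN equals the number of APC events, TP + FP
    equals the number of detections, and TN is 1 exactly when the dive has
    neither events nor detections.
    """
    events = sorted(apc_events(events), key=lambda e: e.start)
    detections = sorted(detections, key=lambda d: d.t_first_peak)
    if not events and not detections:
        return [MatchRecord(dive_id, "TN")], ConfusionCounts(tn=1)

    matched: dict[int, list[DetectedAPC]] = {}
    records: list[MatchRecord] = []
    outside: list[DetectedAPC] = []
    for det in detections:
        event = _assign_event(det, events)
        if event is None:
            outside.append(det)
        else:
            matched.setdefault(id(event), []).append(det)

    tp = fp = fn = 0
    for event in events:
        hits = matched.get(id(event), [])
        if not hits:
            fn += 1
            records.append(MatchRecord(dive_id, "FN", event_start=event.start))
            continue
        tp += 1
        records.append(MatchRecord(dive_id, "TP", hits[0].t_first_peak, event.start))
        for extra in hits[1:]:
            fp += 1
            records.append(MatchRecord(dive_id, "FP_multiple", extra.t_first_peak, event.start))
    for det in outside:
        fp += 1
        records.append(MatchRecord(dive_id, "FP_outside", det.t_first_peak))
    records.sort(key=lambda r: (r.detection_time if r.detection_time is not None else r.event_start or 0.0))
    return records, ConfusionCounts(tp=tp, fp=fp, fn=fn)


def pool_counts(counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Elementwise sum over dives (or any disjoint grouping)."""
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return total


def records_to_frame(records: list[MatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dive_id": r.dive_id,
                "label": r.label,
                "detection_time_s": r.detection_time,
                "event_start_s": r.event_start,
            }
            for r in records
        ],
        columns=["dive_id", "label", "detection_time_s", "event_start_s"],
    )
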