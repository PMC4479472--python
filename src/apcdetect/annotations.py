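"""Video ground-truth event tables.

Animal-borne video supplies the validation reference: each annotated event
is a behavioural episode directed at one potential prey item, with a time
window running from the start of the chase to the end of handling (or end
of chase for misses).  Categories follow the ethogram used for fur-seal
Crittercam footage:

``chase_missed``
    chase with a capture lunge but no prey secured -> unsuccessful APC.
``chase_capture_handling`` / ``chase_capture_no_handling`` / ``capture_no_chase``
    prey secured (with or without visible handling or a preceding chase)
    -> successful APC.
``chase_no_attempt``
    chase abandoned without a capture lunge; not an APC at all, excluded
    from matching and treated as prey-absent context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CATEGORIES",
    "PREY_TYPES",
    "LOCATIONS",
    "VideoEvent",
    "read_events",
    "write_events",
    "classify_success",
    "apc_events",
    "dive_prey_status",
    "events_by_dive",
]

CATEGORIES = (
    "chase_missed",
    "chase_capture_handling",
    "chase_capture_no_handling",
    "capture_no_chase",
    "chase_no_attempt",
)
PREY_TYPES = ("fish", "cephalopod", "stingray", "unknown")
LOCATIONS = ("benthic", "ascent_surface")

_SUCCESSFUL = {"chase_capture_handling", "chase_capture_no_handling", "capture_no_chase"}

COLUMNS = ["dive_id", "start_s", "end_s", "category", "prey_type", "location"]


@dataclass(frozen=True)
class VideoEvent:
    """One annotated behavioural event (times on the deployment clock)."""

    dive_id: int
    start: float
    end: float
    category: str
    prey_type: str = "unknown"
    location: str = "benthic"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"event window must have start < end, got [{self.start}, {self.end}]")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if self.prey_type not in PREY_TYPES:
            raise ValueError(f"unknown prey type {self.prey_type!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown consumption location {self.location!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def classify_success(event: VideoEvent) -> str:
    """``successful`` / ``unsuccessful`` / ``excluded`` for one event.

    A missed capture attempt is an unsuccessful APC; any combination that
    secures the prey is successful; an abandoned chase with no capture
    attempt is excluded from APC accounting entirely.
    """
    if event.category == "chase_missed":
        return "unsuccessful"
    if event.category == "chase_no_attempt":
        return "excluded"
    assert event.category in _SUCCESSFUL
    return "successful"


def apc_events(events: list[VideoEvent]) -> list[VideoEvent]:
    """Events that count as attempted prey captures (excluded ones dropped)."""
    return [e for e in events if classify_success(e) != "excluded"]


def dive_prey_status(events: list[VideoEvent]) -> str:
    """``prey_present`` iff the dive holds at least one non-excluded APC event.

    Abandoned chases alone leave a dive prey-absent: only a capture attempt
    (successful or missed) marks prey as present.
    """
    return "prey_present" if apc_events(events) else "prey_absent"


def write_events(events: list[VideoEvent], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "dive_id": e.dive_id,
                "start_s": e.start,
                "end_s": e.end,
                "category": e.category,
                "prey_type": e.prey_type,
                "location": e.location,
            }
            for e in events
        ],
        columns=COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_events(path) -> list[VideoEvent]:
    """Read an annotation table; events returned sorted by start time.

    Malformed rows (bad category/prey/ordering) raise with the row index;
    overlapping event windows within a dive are kept but warned about, since
    the matching stage then needs its deterministic overlap rule.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    events = []
    for i, row in frame.iterrows():
        try:
            events.append(
                VideoEvent(
                    dive_id=int(row["dive_id"]),
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    category=str(row["category"]),
                    prey_type=str(row["prey_type"]),
                    location=str(row["location"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad event row {i}: {exc}") from exc
    events.sort(key=lambda e: (e.dive_id, e.start))
    by_dive: dict[int, list[VideoEvent]] = {}
    for e in events:
        by_dive.setdefault(e.dive_id, []).append(e)
    for dive_id, evs in by_dive.items():
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"{path}: overlapping events in dive {dive_id} "
                    f"([{a.start}, {a.end}] and [{b.start}, {b.end}]); kept",
                    stacklevel=2,
                )
    events.sort(key=lambda e: e.start)
    return events


def events_by_dive(dives, events: list[VideoEvent]) -> dict[int, list[VideoEvent]]:
    """Assign events to dives by time containment of the event start.

    Events starting outside every dive are dropped with a warning (video
    occasionally spans a surface interval the depth record excludes).
    Returns a dict with an entry for every dive, empty list if none.
    """
    out: dict[int, list[VideoEvent]] = {dv.dive_id: [] for dv in dives}
    for e in events:
        for dv in dives:
            if dv.contains(e.start):
                out[dv.dive_id].append(e)
                break
        else:
            warnings.warn(f"event at t={e.start:.1f}s falls outside every dive; dropped", stacklevel=2)
    return out
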