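"""Respiratory-event annotations and frame-level label generation.

Events are half-open time intervals ``[onset_s, offset_s)`` carrying a
class: 1 = hypopnea (partial airflow reduction), 2 = apnea (near-complete
cessation, aggregating obstructive/central/mixed subtypes). Frame labels
live on an 80 ms grid; a frame belongs to an event iff its center falls
inside the event interval, with apnea taking precedence over hypopnea on
overlap.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .config import FRAME_PERIOD_S

HYPOPNEA = 1
APNEA = 2

#: accepted class spellings -> internal class code
CLASS_ALIASES = {
    "hypopnea": HYPOPNEA,
    "apnea": APNEA,
    "obstructive_apnea": APNEA,
    "central_apnea": APNEA,
    "mixed_apnea": APNEA,
    "1": HYPOPNEA,
    "2": APNEA,
}

CLASS_NAMES = {HYPOPNEA: "hypopnea", APNEA: "apnea"}

_SUBTYPES = {"obstructive", "central", "mixed", "none"}


@dataclass(frozen=True)
class RespiratoryEvent:
    """One scored respiratory event on the night timeline."""

    onset_s: float
    offset_s: float
    cls: int
    subtype: str = "none"

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError(
                f"event offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )
        if self.cls not in (HYPOPNEA, APNEA):
            raise ValueError(f"event class must be 1 (hypopnea) or 2 (apnea), got {self.cls}")
        if self.subtype not in _SUBTYPES:
            raise ValueError(f"unknown event subtype {self.subtype!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventList:
    """Ordered respiratory events for one subject."""

    subject_id: str = ""
    events: list[RespiratoryEvent] = field(default_factory=list)
    total_sleep_s: float | None = None

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.offset_s, e.cls))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[RespiratoryEvent]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def of_class(self, cls: int) -> list[RespiratoryEvent]:
        return [e for e in self.events if e.cls == cls]


@dataclass(frozen=True)
class FrameTimeline:
    """Uniform frame grid: frame i covers [origin + i*p, origin + (i+1)*p)."""

    n_frames: int
    frame_period_s: float = FRAME_PERIOD_S
    origin_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def frame_centers(self) -> np.ndarray:
        return self.origin_s + (np.arange(self.n_frames) + 0.5) * self.frame_period_s

    @classmethod
    def for_duration(cls, duration_s: float, origin_s: float = 0.0,
                     frame_period_s: float = FRAME_PERIOD_S) -> "FrameTimeline":
        # round() guards against float jitter in duration / period
        n = int(round(duration_s / frame_period_s))
        return cls(n_frames=n, frame_period_s=frame_period_s, origin_s=origin_s)


def _parse_class(value: str) -> int:
    key = str(value).strip().lower()
    if key not in CLASS_ALIASES:
        raise ValueError(f"unknown respiratory event class {value!r}")
    return CLASS_ALIASES[key]


def _rows_to_eventlist(rows: Iterable[dict], subject_id: str,
                       total_sleep_s: float | None) -> EventList:
    events = []
    for i, row in enumerate(rows):
        onset = float(row["onset_s"])
        offset = float(row["offset_s"])
        if offset <= onset:
            warnings.warn(
                f"row {i}: rejected event with offset ({offset}) <= onset ({onset})"
            )
            continue
        cls = _parse_class(row["class"])
        subtype = str(row.get("subtype") or "none").strip().lower() or "none"
        events.append(RespiratoryEvent(onset, offset, cls, subtype))
    return EventList(subject_id=subject_id, events=events, total_sleep_s=total_sleep_s)


def load_events(path) -> EventList:
    """Read an event list from CSV (``onset_s,offset_s,class[,subtype]``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        return _rows_to_eventlist(
            payload.get("events", []),
            subject_id=payload.get("subject_id", path.stem),
            total_sleep_s=payload.get("total_sleep_s"),
        )
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"onset_s", "offset_s", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: expected CSV header with columns onset_s,offset_s,class"
            )
        return _rows_to_eventlist(reader, subject_id=path.stem, total_sleep_s=None)


def write_events(ev: EventList, path) -> None:
    """Write events as CSV with 6-decimal second precision (round-trip safe)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "offset_s", "class", "subtype"])
        for e in ev:
            writer.writerow(
                [f"{e.onset_s:.6f}", f"{e.offset_s:.6f}", CLASS_NAMES[e.cls], e.subtype]
            )


def events_to_frame_labels(ev: EventList, tl: FrameTimeline) -> np.ndarray:
    """Rasterize events onto a frame grid (frame-center membership rule).

    A frame gets an event's class iff its center lies inside the half-open
    event interval; apnea overrides hypopnea when events overlap. Events
    extending beyond the timeline are clipped with a warning.
    """
    labels = np.zeros(tl.n_frames, dtype=np.int64)
    t_lo = tl.origin_s
    t_hi = tl.origin_s + tl.duration_s
    p = tl.frame_period_s
    for cls in (HYPOPNEA, APNEA):  # apnea painted last -> precedence
        for e in ev.of_class(cls):
            if e.offset_s <= t_lo or e.onset_s >= t_hi:
                warnings.warn(
                    f"event [{e.onset_s}, {e.offset_s}) lies outside the timeline; skipped"
                )
                continue
            if e.onset_s < t_lo or e.offset_s > t_hi:
                warnings.warn(
                    f"event [{e.onset_s}, {e.offset_s}) clipped to the timeline"
                )
            # centers (i + 0.5) * p + origin in [onset, offset)
            first = int(np.ceil((e.onset_s - t_lo) / p - 0.5))
            last = int(np.ceil((e.offset_s - t_lo) / p - 0.5))  # exclusive
            first = max(first, 0)
            last = min(last, tl.n_frames)
            if last > first:
                labels[first:last] = cls
    return labels
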