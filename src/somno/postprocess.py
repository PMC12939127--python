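"""From window-level frame probabilities to clinically valid events.

Stages, in the mandated order: temporal averaging of overlapping
windows, per-frame argmax (ties resolved toward the lowest class, i.e.
normal), median smoothing (kernel 5, edge replication), run extraction,
merging of same-class events separated by gaps strictly shorter than
3 s (iterated to fixpoint), and finally discarding events shorter than
10 s. Merging precedes duration filtering so fragmented long events are
recovered before the clinical minimum is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .annotations import EventList, FrameTimeline, RespiratoryEvent
from .config import FRAME_PERIOD_S, PostprocessConfig


@dataclass
class NightPrediction:
    """Aggregated full-night model output for one subject."""

    probs: np.ndarray  # (n_frames, 3)
    labels: np.ndarray  # post-smoothing label sequence
    events: EventList
    coverage: np.ndarray  # windows contributing to each frame
    timeline: FrameTimeline


def aggregate_overlaps(window_probs: list[np.ndarray], start_times: list[float],
                       timeline: FrameTimeline,
                       padded_frames: list[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of overlapping window probabilities per night frame.

    ``padded_frames[i]`` marks how many trailing output frames of window i
    came from zero-padding; those are excluded. Returns (probs, coverage).
    """
    n = timeline.n_frames
    n_classes = window_probs[0].shape[1]
    acc = np.zeros((n, n_classes), dtype=np.float64)
    cov = np.zeros(n, dtype=np.int64)
    p = timeline.frame_period_s
    for i, (probs, start) in enumerate(zip(window_probs, start_times)):
        t = probs.shape[0]
        valid = t - (padded_frames[i] if padded_frames else 0)
        f0 = int(round((start - timeline.origin_s) / p))
        f1 = min(f0 + valid, n)
        if f0 < 0 or f0 >= n:
            raise ValueError(f"window start {start}s falls outside the night timeline")
        acc[f0:f1] += probs[:f1 - f0]
        cov[f0:f1] += 1
    if np.any(cov == 0):
        raise ValueError("timeline mismatch: some frames are covered by no window")
    out = acc / cov[:, None]
    out /= out.sum(axis=1, keepdims=True)
    return out, cov


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Per-frame argmax; ties break toward the lowest class index."""
    return np.argmax(probs, axis=1).astype(np.int64)


def median_smooth(labels: np.ndarray, k: int) -> np.ndarray:
    """Centered running median with edge replication (k odd)."""
    if k % 2 == 0 or k < 1:
        raise ValueError("median kernel must be odd and >= 1")
    if k == 1:
        return np.asarray(labels, dtype=np.int64).copy()
    return median_filter(np.asarray(labels, dtype=np.int64), size=k,
                         mode="nearest")


def extract_events(labels: np.ndarray, timeline: FrameTimeline,
                   subject_id: str = "") -> EventList:
    """Maximal runs of identical nonzero labels become events."""
    labels = np.asarray(labels, dtype=np.int64)
    p = timeline.frame_period_s
    events = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(labels)]])
    for s, e in zip(starts, ends):
        cls = int(labels[s])
        if cls:
            events.append(RespiratoryEvent(
                onset_s=timeline.origin_s + s * p,
                offset_s=timeline.origin_s + e * p,
                cls=cls,
            ))
    return EventList(subject_id=subject_id, events=events,
                     total_sleep_s=timeline.duration_s)


def merge_events(ev: EventList, merge_gap_s: float) -> EventList:
    """Coalesce same-class neighbors with gaps strictly below merge_gap_s.

    A left-to-right pass repeated to fixpoint, so transitive chains merge;
    different classes never merge.
    """
    events = list(ev.events)
    changed = True
    while changed:
        changed = False
        merged: list[RespiratoryEvent] = []
        for e in sorted(events, key=lambda x: (x.onset_s, x.offset_s)):
            if (merged and merged[-1].cls == e.cls
                    and e.onset_s - merged[-1].offset_s < merge_gap_s):
                prev = merged.pop()
                merged.append(RespiratoryEvent(
                    onset_s=prev.onset_s,
                    offset_s=max(prev.offset_s, e.offset_s),
                    cls=e.cls, subtype=prev.subtype,
                ))
                changed = True
            else:
                merged.append(e)
        events = merged
    return EventList(subject_id=ev.subject_id, events=events,
                     total_sleep_s=ev.total_sleep_s)


def filter_duration(ev: EventList, min_duration_s: float) -> EventList:
    """Keep events lasting at least min_duration_s."""
    kept = [e for e in ev if e.duration_s >= min_duration_s]
    return EventList(subject_id=ev.subject_id, events=kept,
                     total_sleep_s=ev.total_sleep_s)


def detect_events(night_probs: np.ndarray, timeline: FrameTimeline,
                  cfg: PostprocessConfig | None = None,
                  coverage: np.ndarray | None = None,
                  subject_id: str = "") -> NightPrediction:
    """argmax -> median smoothing -> runs -> gap merging -> duration filter."""
    cfg = cfg or PostprocessConfig()
    labels = median_smooth(argmax_labels(night_probs), cfg.median_kernel)
    events = extract_events(labels, timeline, subject_id=subject_id)
    events = merge_events(events, cfg.merge_gap_s)
    events = filter_duration(events, cfg.min_duration_s)
    if coverage is None:
        coverage = np.ones(timeline.n_frames, dtype=np.int64)
    return NightPrediction(probs=night_probs, labels=labels, events=events,
                           coverage=coverage, timeline=timeline)
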