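"""End-to-end orchestration: synthetic nights -> features -> training ->
full-night detection -> three-level evaluation.

These helpers glue the stage modules together for scripted experiments
and the CLI; each one is a thin composition with no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import EventList, FrameTimeline, events_to_frame_labels
from .config import FRAME_PERIOD_S, PostprocessConfig, RunConfig
from .evaluation import (agreement_stats, localization_metrics, match_events,
                         patient_indices)
from .model import DualStreamCRNN
from .postprocess import NightPrediction, aggregate_overlaps, detect_events
from .signal_features import AudioRecording, FeatureConfig, SegmentFeatures, featurize_recording
from .synthetic import SyntheticNight
from .training import Example


def label_window(truth: EventList, start_s: float, window_s: float) -> np.ndarray:
    """Frame labels for one analysis window on the 80 ms output grid."""
    n_frames = int(round(window_s / FRAME_PERIOD_S))
    tl = FrameTimeline(n_frames=n_frames, origin_s=start_s)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # windows legitimately clip events
        return events_to_frame_labels(truth, tl)


def night_to_examples(night: SyntheticNight, cfg: FeatureConfig,
                      keep_fraction_background: float = 1.0,
                      rng: np.random.Generator | None = None) -> list[Example]:
    """Featurize a night into labeled training windows.

    ``keep_fraction_background`` optionally subsamples windows containing
    no event frames, a standard rebalancing step for sparse event data.
    """
    feats = featurize_recording(night.recording, cfg, inference=False)
    examples: list[Example] = []
    for f in feats:
        labels = label_window(night.truth, f.start_s, cfg.window_s)
        if labels.max() == 0 and keep_fraction_background < 1.0:
            if rng is None or rng.random() > keep_fraction_background:
                continue
        examples.append((f, labels))
    return examples


def detect_night(model: DualStreamCRNN, rec: AudioRecording,
                 feature_cfg: FeatureConfig,
                 post_cfg: PostprocessConfig | None = None,
                 subject_id: str = "",
                 batch_size: int = 4) -> NightPrediction:
    """Featurize, predict, aggregate overlaps and post-process one night."""
    feats = featurize_recording(rec, feature_cfg, inference=True)
    if not feats:
        raise ValueError("recording too short to form any analysis window")
    probs = model.predict_proba(feats, batch_size=batch_size)
    total_frames = int(rec.duration_s / FRAME_PERIOD_S)
    timeline = FrameTimeline(n_frames=total_frames)
    # padded_frames counts 10 ms mel frames; outputs are pooled 8x to 80 ms
    pool = model.cfg.time_pool_total
    night_probs, coverage = aggregate_overlaps(
        probs, [f.start_s for f in feats], timeline,
        padded_frames=[-(-f.padded_frames // pool) for f in feats],
    )
    return detect_events(night_probs, timeline, post_cfg, coverage=coverage,
                         subject_id=subject_id)


@dataclass
class CohortEvaluation:
    per_subject: list[dict]
    ahi_agreement: object
    apnea_recall: float | None
    localization: dict


def evaluate_cohort(model: DualStreamCRNN, nights: list[SyntheticNight],
                    run_cfg: RunConfig, iou_recall_min: float = 0.5,
                    batch_size: int = 4) -> CohortEvaluation:
    """Detect on each night and compare against the planted truth.

    Reports per-subject AHI pairs, the AHI agreement statistics, the
    recall of planted apneas at the requested IoU, and pooled
    localization metrics.
    """
    from .annotations import APNEA

    per_subject = []
    audio_ahi, psg_ahi = [], []
    apnea_hits = apnea_total = 0
    pooled_pairs = []
    for i, night in enumerate(nights):
        pred = detect_night(model, night.recording, run_cfg.features,
                            run_cfg.postprocess, subject_id=f"synthetic-{i}",
                            batch_size=batch_size)
        hours = (night.truth.total_sleep_s or night.recording.duration_s) / 3600.0
        audio = patient_indices(pred.events, hours)
        ref = patient_indices(night.truth, hours)
        audio_ahi.append(audio.ahi)
        psg_ahi.append(ref.ahi)
        ms = match_events(night.truth, pred.events, run_cfg.match)
        pooled_pairs.extend(ms.pairs)
        for g, p, v in ms.pairs:
            if g.cls == APNEA and v >= iou_recall_min:
                apnea_hits += 1
        apnea_total += len(night.truth.of_class(APNEA))
        per_subject.append({
            "subject": f"synthetic-{i}",
            "audio_ahi": audio.ahi, "psg_ahi": ref.ahi,
            "n_pred_events": len(pred.events), "n_true_events": len(night.truth),
        })
    agreement = agreement_stats(audio_ahi, psg_ahi) if len(nights) >= 3 else None
    from .evaluation import MatchSet
    pooled = MatchSet(pairs=pooled_pairs, unmatched_gt=[], unmatched_pred=[])
    loc = localization_metrics(pooled) if pooled_pairs else {}
    recall = apnea_hits / apnea_total if apnea_total else None
    return CohortEvaluation(per_subject=per_subject, ahi_agreement=agreement,
                            apnea_recall=recall, localization=loc)
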