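"""Post-processing pipeline vs a brute-force interval-algebra oracle."""

import numpy as np
import pytest

from somno.annotations import (APNEA, HYPOPNEA, EventList, FrameTimeline,
                               RespiratoryEvent, events_to_frame_labels)
from somno.config import PostprocessConfig
from somno.postprocess import (aggregate_overlaps, argmax_labels,
                               detect_events, extract_events, filter_duration,
                               median_smooth, merge_events)

P = 0.08


# ---------------------------------------------------------------------------
# brute-force oracle: direct interval algebra on label sequences
# ---------------------------------------------------------------------------

def oracle_pipeline(labels, k, merge_gap_s, min_duration_s):
    """Reference implementation by direct definition, O(n*k)."""
    labels = np.asarray(labels)
    n = len(labels)
    # centered median with edge replication
    smoothed = np.empty(n, dtype=int)
    half = k // 2
    for i in range(n):
        idx = np.clip(np.arange(i - half, i + half + 1), 0, n - 1)
        smoothed[i] = int(np.median(labels[idx]))
    # runs of identical nonzero labels
    events = []
    i = 0
    while i < n:
        if smoothed[i] != 0:
            j = i
            while j < n and smoothed[j] == smoothed[i]:
                j += 1
            events.append([i * P, j * P, int(smoothed[i])])
            i = j
        else:
            i += 1
    # merge to fixpoint
    changed = True
    while changed:
        changed = False
        out = []
        for e in events:
            if out and out[-1][2] == e[2] and e[0] - out[-1][1] < merge_gap_s:
                out[-1][1] = max(out[-1][1], e[1])
                changed = True
            else:
                out.append(list(e))
        events = out
    # duration filter
    return [tuple(e) for e in events if e[1] - e[0] >= min_duration_s]


def events_to_tuples(ev):
    return [(round(e.onset_s, 6), round(e.offset_s, 6), e.cls) for e in ev]


class TestAggregateOverlaps:
    def test_mean_of_two_windows(self):
        tl = FrameTimeline(n_frames=750 + 375)  # 90 s
        w1 = np.tile([0.8, 0.1, 0.1], (750, 1))
        w2 = np.tile([0.6, 0.2, 0.2], (750, 1))
        probs, cov = aggregate_overlaps([w1, w2], [0.0, 30.0], tl)
        np.testing.assert_allclose(probs[0], [0.8, 0.1, 0.1])
        np.testing.assert_allclose(probs[400], [0.7, 0.15, 0.15])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_coverage_counts_150s_night(self):
        tl = FrameTimeline(n_frames=1875)  # 150 s
        wins = [np.full((750, 3), 1 / 3) for _ in range(4)]
        starts = [0.0, 30.0, 60.0, 90.0]
        _, cov = aggregate_overlaps(wins, starts, tl)
        frames = np.arange(1875) * P
        expected = np.where((frames < 30) | (frames >= 120), 1, 2)
        np.testing.assert_array_equal(cov, expected)

    def test_padded_tail_frames_excluded(self):
        tl = FrameTimeline(n_frames=937)  # 75 s night, whole frames only
        w1 = np.tile([1.0, 0.0, 0.0], (750, 1))
        w2 = np.tile([0.0, 1.0, 0.0], (750, 1))
        probs, cov = aggregate_overlaps([w1, w2], [0.0, 30.0], tl,
                                        padded_frames=[0, 188])
        assert cov[0] == 1 and cov[400] == 2
        # beyond 60 s only window 2's un-padded frames contribute
        np.testing.assert_allclose(probs[800], [0.0, 1.0, 0.0])

    def test_uncovered_frame_raises(self):
        tl = FrameTimeline(n_frames=1000)
        with pytest.raises(ValueError, match="timeline"):
            aggregate_overlaps([np.full((750, 3), 1 / 3)], [0.0], tl)


class TestMedianSmooth:
    def test_isolated_spike_removed(self):
        labels = np.array([0, 0, 0, 2, 0, 0, 0])
        np.testing.assert_array_equal(median_smooth(labels, 5), np.zeros(7))

    def test_constant_sequence_unchanged(self):
        labels = np.full(20, 1)
        np.testing.assert_array_equal(median_smooth(labels, 5), labels)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 3, size=rng.integers(5, 200))
            for k in (3, 5, 7):
                got = median_smooth(labels, k)
                n, half = len(labels), k // 2
                ref = [int(np.median(labels[np.clip(np.arange(i - half, i + half + 1),
                                                    0, n - 1)]))
                       for i in range(n)]
                np.testing.assert_array_equal(got, ref)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(np.zeros(5, dtype=int), 4)


class TestExtractEvents:
    def test_all_zero_empty(self):
        tl = FrameTimeline(n_frames=100)
        assert len(extract_events(np.zeros(100, dtype=int), tl)) == 0

    def test_run_bounds_scaled_to_seconds(self):
        tl = FrameTimeline(n_frames=750)
        labels = np.zeros(750, dtype=int)
        labels[125:312] = APNEA
        ev = extract_events(labels, tl)
        assert len(ev) == 1
        assert ev[0].onset_s == pytest.approx(10.0)
        assert ev[0].offset_s == pytest.approx(24.96)
        assert ev[0].cls == APNEA

    def test_class_change_splits_runs(self):
        tl = FrameTimeline(n_frames=4)
        ev = extract_events(np.array([1, 1, 2, 2]), tl)
        assert len(ev) == 2
        assert [e.cls for e in ev] == [HYPOPNEA, APNEA]


class TestMergeEvents:
    def test_small_gap_merges(self):
        ev = EventList(events=[RespiratoryEvent(0, 12, APNEA),
                               RespiratoryEvent(14, 30, APNEA)])
        out = merge_events(ev, 3.0)
        assert events_to_tuples(out) == [(0.0, 30.0, APNEA)]

    def test_exact_gap_not_merged(self):
        ev = EventList(events=[RespiratoryEvent(0, 12, APNEA),
                               RespiratoryEvent(15.0, 30, APNEA)])
        assert len(merge_events(ev, 3.0)) == 2

    def test_chain_merges_to_fixpoint(self):
        ev = EventList(events=[RespiratoryEvent(0, 12, APNEA),
                               RespiratoryEvent(14, 26, APNEA),
                               RespiratoryEvent(28, 40, APNEA)])
        out = merge_events(ev, 3.0)
        assert events_to_tuples(out) == [(0.0, 40.0, APNEA)]

    def test_different_classes_never_merge(self):
        ev = EventList(events=[RespiratoryEvent(0, 12, APNEA),
                               RespiratoryEvent(13, 25, HYPOPNEA)])
        assert len(merge_events(ev, 3.0)) == 2


class TestFilterDuration:
    def test_boundary_cases(self):
        ev = EventList(events=[RespiratoryEvent(0, 9.92, APNEA),
                               RespiratoryEvent(20, 30.0, APNEA)])
        out = filter_duration(ev, 10.0)
        assert events_to_tuples(out) == [(20.0, 30.0, APNEA)]

    def test_count_matches_recount(self, rng):
        events = []
        t = 0.0
        for _ in range(50):
            d = float(rng.uniform(5, 20))
            events.append(RespiratoryEvent(t, t + d, APNEA))
            t += d + 30
        ev = EventList(events=events)
        out = filter_duration(ev, 10.0)
        assert len(out) == sum(1 for e in events if e.duration_s >= 10.0)


class TestDetectEvents:
    def _probs_from_labels(self, labels, p=0.9):
        probs = np.full((len(labels), 3), (1 - p) / 2)
        probs[np.arange(len(labels)), labels] = p
        return probs

    def test_single_block_recovered(self):
        tl = FrameTimeline(n_frames=750)
        labels = np.zeros(750, dtype=int)
        labels[250:500] = APNEA  # 20 s starting at 20 s
        pred = detect_events(self._probs_from_labels(labels), tl)
        assert len(pred.events) == 1
        e = pred.events[0]
        assert abs(e.onset_s - 20.0) <= 0.16
        assert abs(e.offset_s - 40.0) <= 0.16
        assert e.cls == APNEA

    def test_merge_precedes_duration_filter(self):
        """Two 8 s blocks 2 s apart survive as one 18 s merged event."""
        tl = FrameTimeline(n_frames=750)
        labels = np.zeros(750, dtype=int)
        labels[125:225] = APNEA            # [10, 18) s
        labels[250:350] = APNEA            # [20, 28) s
        pred = detect_events(self._probs_from_labels(labels), tl)
        assert len(pred.events) == 1
        assert pred.events[0].duration_s == pytest.approx(18.0, abs=0.2)

    def test_uniform_probabilities_yield_no_events(self):
        tl = FrameTimeline(n_frames=750)
        pred = detect_events(np.full((750, 3), 1 / 3), tl)
        assert len(pred.events) == 0  # argmax ties resolve to normal

    def test_pipeline_idempotence(self, rng):
        tl = FrameTimeline(n_frames=2000)
        labels = np.zeros(2000, dtype=int)
        t = 100
        while t < 1800:
            d = int(rng.uniform(130, 300))
            labels[t:t + d] = int(rng.choice([1, 2]))
            t += d + int(rng.uniform(260, 400))
        pred = detect_events(self._probs_from_labels(labels), tl)
        again = detect_events(self._probs_from_labels(pred.labels), tl)
        assert events_to_tuples(pred.events) == events_to_tuples(again.events)

    def test_equivalence_with_brute_force_oracle(self, rng):
        cfg = PostprocessConfig()
        for trial in range(1000):
            n = int(rng.integers(50, 400))
            # block-structured noisy labels exercise all stages
            labels = np.zeros(n, dtype=int)
            t = 0
            while t < n:
                run = int(rng.integers(1, 80))
                labels[t:t + run] = int(rng.integers(0, 3))
                t += run
            flip = rng.random(n) < 0.05
            labels[flip] = rng.integers(0, 3, size=int(flip.sum()))
            tl = FrameTimeline(n_frames=n)
            pred = detect_events(self._probs_from_labels(labels), tl)
            ref = oracle_pipeline(labels, cfg.median_kernel, cfg.merge_gap_s,
                                  cfg.min_duration_s)
            got = [(e.onset_s, e.offset_s, e.cls) for e in pred.events]
            np.testing.assert_allclose(
                np.asarray(got, dtype=float).reshape(-1, 3),
                np.asarray(ref, dtype=float).reshape(-1, 3), atol=1e-9,
                err_msg=f"trial {trial}")


class TestRoundTrip:
    def test_events_survive_rasterize_extract_cycle(self, rng):
        """>=10 s events round-trip with <= 0.08 s boundary error."""
        tl = FrameTimeline(n_frames=int(600 / P))
        events = []
        t = 20.0
        while True:
            d = float(rng.uniform(10, 35))
            if t + d > tl.duration_s - 20:
                break
            events.append(RespiratoryEvent(round(t, 3), round(t + d, 3),
                                           int(rng.choice([1, 2]))))
            t += d + float(rng.uniform(20, 40))
        ev = EventList(events=events)
        labels = events_to_frame_labels(ev, tl)
        back = extract_events(labels, tl)
        assert len(back) == len(ev)
        for orig, rec in zip(ev, back):
            assert rec.cls == orig.cls
            assert abs(rec.onset_s - orig.onset_s) <= P + 1e-9
            assert abs(rec.offset_s - orig.offset_s) <= P + 1e-9
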