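"""Frame, event and patient-level metric tests with independent oracles."""

import itertools

import numpy as np
import pytest

from somno.annotations import APNEA, HYPOPNEA, EventList, RespiratoryEvent
from somno.config import MatchConfig
from somno.evaluation import (agreement_stats, bootstrap_ci, clopper_pearson,
                              cohen_kappa, error_taxonomy, frame_metrics, iou,
                              localization_metrics, mann_whitney_auc,
                              match_events, patient_indices, screening_report)


def ev(onset, offset, cls=APNEA):
    return RespiratoryEvent(onset, offset, cls)


class TestIoU:
    def test_identical(self):
        assert iou((0, 10), (0, 10)) == 1.0

    def test_disjoint(self):
        assert iou((0, 10), (20, 30)) == 0.0

    def test_partial_overlap(self):
        assert iou((0, 10), (5, 15)) == pytest.approx(1 / 3)

    def test_event_objects_accepted(self):
        assert iou(ev(0, 20), ev(2, 19)) == pytest.approx(17 / 20)


class TestMatchEvents:
    def test_two_pair_example(self):
        gt = EventList(events=[ev(0, 20), ev(30, 45)])
        pred = EventList(events=[ev(2, 19), ev(28, 46), ev(100, 115)])
        ms = match_events(gt, pred)
        assert len(ms.pairs) == 2
        ious = sorted(v for _, _, v in ms.pairs)
        assert ious[0] == pytest.approx(15 / 18)  # [30,45) vs [28,46)
        assert ious[1] == pytest.approx(17 / 20)  # [0,20) vs [2,19)
        assert len(ms.unmatched_pred) == 1
        assert ms.unmatched_pred[0].onset_s == 100

    def test_greedy_keeps_highest_iou(self):
        gt = EventList(events=[ev(0, 10)])
        pred = EventList(events=[ev(0, 6), ev(5, 10)])
        ms = match_events(gt, pred)
        assert len(ms.pairs) == 1
        assert ms.pairs[0][1].offset_s == 6  # IoU 0.6 beats 0.5
        assert ms.unmatched_pred[0].onset_s == 5

    def test_empty_prediction_all_unmatched(self):
        gt = EventList(events=[ev(0, 10), ev(20, 35)])
        ms = match_events(gt, EventList())
        assert not ms.pairs and len(ms.unmatched_gt) == 2

    def test_below_threshold_not_matched(self):
        gt = EventList(events=[ev(0, 100)])
        pred = EventList(events=[ev(99, 104)])  # IoU = 1/104 < 0.1
        ms = match_events(gt, pred, MatchConfig(iou_min=0.1))
        assert not ms.pairs

    def test_matching_is_class_agnostic(self):
        gt = EventList(events=[ev(0, 20, HYPOPNEA)])
        pred = EventList(events=[ev(1, 21, APNEA)])
        assert len(match_events(gt, pred).pairs) == 1

    def test_one_to_one_and_order_invariant(self, rng):
        """Greedy matching is stable under input permutation."""
        for _ in range(30):
            gts, preds = [], []
            t = 0.0
            for _ in range(rng.integers(2, 10)):
                t += rng.uniform(0, 15)
                d = rng.uniform(10, 30)
                gts.append(ev(t, t + d, int(rng.choice([1, 2]))))
                if rng.random() < 0.8:
                    j = rng.uniform(-5, 5)
                    preds.append(ev(max(0, t + j), t + d + rng.uniform(-5, 5) + 1,
                                    int(rng.choice([1, 2]))))
                t += d
            gt = EventList(events=gts)
            ms1 = match_events(gt, EventList(events=preds))
            perm = [preds[i] for i in rng.permutation(len(preds))]
            ms2 = match_events(gt, EventList(events=perm))
            key = lambda ms: sorted((g.onset_s, p.onset_s) for g, p, _ in ms.pairs)
            assert key(ms1) == key(ms2)
            # one-to-one
            for ms in (ms1, ms2):
                assert len({id(g) for g, _, _ in ms.pairs}) == len(ms.pairs)
                assert len({id(p) for _, p, _ in ms.pairs}) == len(ms.pairs)


class TestLocalization:
    def test_perfect_predictions(self):
        gt = EventList(events=[ev(0, 20), ev(30, 45)])
        ms = match_events(gt, gt)
        loc = localization_metrics(ms)
        assert loc["mean_iou"] == pytest.approx(1.0)
        assert loc["onset_mae_s"] == 0.0 and loc["offset_mae_s"] == 0.0

    def test_two_pair_example_values(self):
        gt = EventList(events=[ev(0, 20), ev(30, 45)])
        pred = EventList(events=[ev(2, 19), ev(28, 46)])
        loc = localization_metrics(match_events(gt, pred))
        assert loc["onset_mae_s"] == pytest.approx(2.0)
        assert loc["offset_mae_s"] == pytest.approx(1.0)
        assert loc["mean_iou"] == pytest.approx((17 / 20 + 15 / 18) / 2)

    def test_no_pairs_reported_missing(self):
        ms = match_events(EventList(events=[ev(0, 10)]), EventList())
        with pytest.warns(UserWarning):
            loc = localization_metrics(ms)
        assert loc["mean_iou"] is None


class TestErrorTaxonomy:
    def test_all_correct(self):
        gt = EventList(events=[ev(0, 20, APNEA), ev(40, 55, HYPOPNEA)])
        counts = error_taxonomy(match_events(gt, gt))
        assert counts["correct"] == 2
        assert sum(v for k, v in counts.items() if k != "correct") == 0

    def test_cross_class_confusion_counted(self):
        gt = EventList(events=[ev(0, 20, HYPOPNEA)])
        pred = EventList(events=[ev(0, 20, APNEA)])
        counts = error_taxonomy(match_events(gt, pred))
        assert counts["hypopnea_as_apnea"] == 1

    def test_planted_error_mixture(self):
        gt = EventList(events=[
            ev(0, 20, APNEA),        # matched, correct
            ev(50, 65, HYPOPNEA),    # matched as apnea
            ev(100, 115, HYPOPNEA),  # missed
            ev(150, 170, APNEA),     # missed
        ])
        pred = EventList(events=[
            ev(1, 21, APNEA),
            ev(51, 66, APNEA),
            ev(200, 215, HYPOPNEA),  # false event
            ev(250, 270, APNEA),     # false event
        ])
        counts = error_taxonomy(match_events(gt, pred))
        assert counts == {"correct": 1, "hypopnea_as_apnea": 1,
                          "apnea_as_hypopnea": 0,
                          "hypopnea_as_normal": 1, "apnea_as_normal": 1,
                          "normal_as_hypopnea": 1, "normal_as_apnea": 1}


class TestFrameMetrics:
    def test_hand_confusion_example(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 2, 0]
        rep = frame_metrics(y_true, y_pred)
        assert rep.f1[0] == pytest.approx(2 * 0.5 * 0.5)  # p=1/2, r=1/2
        assert rep.f1[1] == pytest.approx(0.8)
        assert rep.f1[2] == pytest.approx(2 / 3)
        assert rep.macro_f1 == pytest.approx((0.5 + 0.8 + 2 / 3) / 3, abs=1e-4)
        assert rep.accuracy == pytest.approx(4 / 6)

    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 3, 100)
        rep = frame_metrics(y, y)
        assert rep.macro_f1 == 1.0 and rep.accuracy == 1.0

    def test_agrees_with_sklearn_on_random_pairs(self, rng):
        from sklearn.metrics import confusion_matrix, f1_score
        for _ in range(200):
            n = int(rng.integers(10, 300))
            y_true = rng.integers(0, 3, n)
            y_pred = rng.integers(0, 3, n)
            rep = frame_metrics(y_true, y_pred)
            np.testing.assert_array_equal(
                rep.confusion, confusion_matrix(y_true, y_pred, labels=[0, 1, 2]))
            present = (set(np.unique(y_true)) | set(np.unique(y_pred)))
            if len(present) == 3 and all(f is not None for f in rep.f1):
                sk = f1_score(y_true, y_pred, average="macro")
                assert rep.macro_f1 == pytest.approx(sk, abs=1e-12)

    def test_absent_class_reported_missing_not_zero(self):
        rep = frame_metrics([0, 0, 0], [0, 0, 0])
        assert rep.precision[1] is None and rep.recall[2] is None
        assert rep.f1[1] is None and rep.f1[2] is None
        assert rep.macro_f1 == 1.0  # only the defined class contributes

    def test_unretrieved_present_class_scores_zero_f1(self):
        # class 2 exists in the truth but is never predicted: its F1 is 0
        # (not excluded), so degenerate all-majority predictions cannot win
        # macro-F1 model selection
        rep = frame_metrics([0, 0, 2, 2], [0, 0, 0, 0])
        assert rep.f1[2] == 0.0
        # class 0: p=1/2, r=1 -> F1 = 2/3; macro over {0, 2} = 1/3
        assert rep.macro_f1 == pytest.approx(1 / 3)
        from sklearn.metrics import f1_score
        sk = f1_score([0, 0, 2, 2], [0, 0, 0, 0], labels=[0, 2],
                      average="macro", zero_division=0)
        assert rep.macro_f1 == pytest.approx(sk)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frame_metrics([0, 1], [0])


class TestPatientIndices:
    def test_basic_rate(self):
        ev_list = EventList(events=[ev(i * 100, i * 100 + 15) for i in range(30)])
        assert patient_indices(ev_list, 6.0).ahi == pytest.approx(5.0)

    def test_component_indices(self):
        events = ([ev(i * 100, i * 100 + 12, APNEA) for i in range(17)]
                  + [ev(5000 + i * 100, 5000 + i * 100 + 12, HYPOPNEA)
                     for i in range(13)])
        s = patient_indices(EventList(events=events), 5.0)
        assert s.ahi == pytest.approx(6.0)
        assert s.ai == pytest.approx(3.4)
        assert s.hi == pytest.approx(2.6)
        assert s.ahi == pytest.approx(s.ai + s.hi)

    def test_empty_list_zero(self):
        assert patient_indices(EventList(), 7.5).ahi == 0.0

    def test_nonpositive_sleep_rejected(self):
        with pytest.raises(ValueError):
            patient_indices(EventList(), 0.0)


class TestAgreement:
    def test_identical_series(self):
        x = np.array([5.0, 20.0, 40.0, 10.0])
        rep = agreement_stats(x, x)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == 0.0 and rep.bias == 0.0

    def test_constant_offset(self):
        x = np.array([5.0, 20.0, 40.0])
        rep = agreement_stats(x + 2, x)
        assert rep.mae == pytest.approx(2.0)
        assert rep.bias == pytest.approx(2.0)
        assert rep.loa_high - rep.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_loa_from_sample_sd(self):
        # d = {0, 2, 4}: bias 2, sample SD 2 -> LoA 2 +/- 3.92
        audio = np.array([10.0, 22.0, 34.0])
        psg = np.array([10.0, 20.0, 30.0])
        rep = agreement_stats(audio, psg)
        assert rep.bias == pytest.approx(2.0)
        assert rep.loa_low == pytest.approx(-1.92)
        assert rep.loa_high == pytest.approx(5.92)

    def test_zero_variance_r_missing(self):
        with pytest.warns(UserWarning):
            rep = agreement_stats(np.full(4, 3.0), np.array([1.0, 2, 3, 4]))
        assert rep.pearson_r is None


class TestScreening:
    @staticmethod
    def _series(tp, fn, fp, tn, threshold):
        """AHI pairs realizing the requested confusion counts."""
        psg, audio = [], []
        psg += [threshold + 5] * tp;  audio += [threshold + 5] * tp
        psg += [threshold + 5] * fn;  audio += [threshold - 2] * fn
        psg += [threshold - 2] * fp;  audio += [threshold + 5] * fp
        psg += [threshold - 2] * tn;  audio += [threshold - 3] * tn
        return np.array(audio), np.array(psg)

    @pytest.mark.parametrize("tp,fn,fp,tn,kappa", [
        (50, 1, 1, 8, 0.869),
        (34, 4, 2, 20, 0.789),
        (25, 3, 0, 32, 0.899),
    ])
    def test_kappa_from_confusion_counts(self, tp, fn, fp, tn, kappa):
        from sklearn.metrics import cohen_kappa_score
        audio, psg = self._series(tp, fn, fp, tn, 15.0)
        rep = screening_report(audio, psg, 15.0)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (tp, fn, fp, tn)
        assert round(rep.kappa, 3) == pytest.approx(kappa)
        # cross-check against sklearn on the binarized labels
        sk = cohen_kappa_score(psg >= 15.0, audio >= 15.0)
        assert rep.kappa == pytest.approx(sk, abs=1e-12)

    def test_npv_cell(self):
        audio, psg = self._series(25, 3, 0, 32, 30.0)
        rep = screening_report(audio, psg, 30.0)
        assert rep.npv == pytest.approx(91.43, abs=0.005)

    def test_metric_definitions(self):
        audio, psg = self._series(8, 2, 1, 9, 15.0)
        rep = screening_report(audio, psg, 15.0)
        assert rep.sensitivity == pytest.approx(80.0)
        assert rep.specificity == pytest.approx(90.0)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.ppv == pytest.approx(100 * 8 / 9)
        assert rep.npv == pytest.approx(100 * 9 / 11)

    def test_kappa_range_and_diagonal(self):
        assert cohen_kappa(10, 0, 0, 10) == 1.0
        assert -1 <= cohen_kappa(0, 10, 10, 0) <= 1

    def test_single_class_reference_missing_metrics(self):
        audio = np.array([10.0, 20.0, 30.0])
        psg = np.array([20.0, 25.0, 30.0])
        with pytest.warns(UserWarning):
            rep = screening_report(audio, psg, 5.0)
        assert rep.specificity is None

    def test_auc_separable_and_sklearn_equivalence(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        labels = scores >= 5
        assert mann_whitney_auc(scores, labels) == 1.0
        for _ in range(50):
            scores = rng.normal(size=30).round(1)  # rounding forces ties
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestBootstrap:
    def test_constant_data_zero_width(self):
        ci = bootstrap_ci(lambda x: float(np.mean(x)), np.full(20, 3.0),
                          n_boot=200, seed=0)
        assert ci == (3.0, 3.0)

    def test_same_seed_reproducible(self, rng):
        x = rng.normal(size=50)
        a = bootstrap_ci(lambda v: float(np.mean(v)), x, n_boot=300, seed=7)
        b = bootstrap_ci(lambda v: float(np.mean(v)), x, n_boot=300, seed=7)
        assert a == b

    def test_normal_theory_width(self):
        x = np.random.default_rng(42).normal(size=200)
        lo, hi = bootstrap_ci(lambda v: float(np.mean(v)), x,
                              n_boot=1000, seed=1)
        assert lo < 0 < hi
        expected = 2 * 1.96 / np.sqrt(200)
        assert abs((hi - lo) - expected) / expected < 0.2


class TestClopperPearson:
    def test_all_successes_lower_bound(self):
        lo, hi = clopper_pearson(11, 11)
        assert hi == pytest.approx(100.0)
        assert lo == pytest.approx(100 * 0.025 ** (1 / 11), abs=0.05)
        assert round(lo, 1) == 71.5

    def test_zero_successes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 10)), abs=0.01)
        assert hi == pytest.approx(30.85, abs=0.01)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_level_limit(self):
        lo99, _ = clopper_pearson(11, 11, level=99.9)
        lo95, _ = clopper_pearson(11, 11, level=95.0)
        assert lo99 < lo95  # wider interval at higher confidence
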