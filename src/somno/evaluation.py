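"""Three-level evaluation: frames, events, and patients.

Frame level: per-class precision/recall/F1 from the 3x3 confusion
matrix, macro averages, overall accuracy.

Event level: greedy one-to-one matching of predicted to reference
events by temporal IoU (acceptance threshold 0.1, class-agnostic),
mean IoU and onset/offset MAE over matched pairs, and an error
taxonomy separating class confusions from missed and spurious events.

Patient level: apnea-hypopnea/apnea/hypopnea indices (events per hour
of sleep), Pearson/MAE/Bland-Altman agreement between audio-derived and
reference AHI series, and screening statistics (sensitivity,
specificity, accuracy, PPV, NPV, Cohen's kappa, rank-statistic AUC)
at the clinical thresholds 5/15/30 events/h, with bootstrap or exact
Clopper-Pearson confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .annotations import APNEA, HYPOPNEA, EventList, RespiratoryEvent
from .config import MatchConfig


# ---------------------------------------------------------------------------
# event-level
# ---------------------------------------------------------------------------

def iou(a: tuple[float, float] | RespiratoryEvent,
        b: tuple[float, float] | RespiratoryEvent) -> float:
    """Temporal intersection-over-union of two intervals; 0 when disjoint."""
    a0, a1 = (a.onset_s, a.offset_s) if isinstance(a, RespiratoryEvent) else a
    b0, b1 = (b.onset_s, b.offset_s) if isinstance(b, RespiratoryEvent) else b
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    if inter == 0.0:
        return 0.0
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union


@dataclass
class MatchSet:
    pairs: list[tuple[RespiratoryEvent, RespiratoryEvent, float]]
    unmatched_gt: list[RespiratoryEvent]
    unmatched_pred: list[RespiratoryEvent]


def match_events(gt: EventList, pred: EventList,
                 cfg: MatchConfig | None = None) -> MatchSet:
    """Greedy one-to-one IoU matching, class-agnostic.

    Candidate pairs with IoU >= iou_min are taken in order of descending
    IoU (ties: earlier reference onset, then earlier predicted onset) and
    accepted when neither event is already matched.
    """
    cfg = cfg or MatchConfig()
    candidates = []
    for gi, g in enumerate(gt):
        for pi, p in enumerate(pred):
            v = iou(g, p)
            if v >= cfg.iou_min and v > 0:
                candidates.append((v, g.onset_s, p.onset_s, gi, pi))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for v, _, _, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gt[gi], pred[pi], v))
    unmatched_gt = [g for i, g in enumerate(gt) if i not in used_g]
    unmatched_pred = [p for i, p in enumerate(pred) if i not in used_p]
    return MatchSet(pairs=pairs, unmatched_gt=unmatched_gt, unmatched_pred=unmatched_pred)


def localization_metrics(ms: MatchSet) -> dict:
    """Mean IoU and onset/offset MAE (s) over matched pairs."""
    if not ms.pairs:
        warnings.warn("no matched pairs; localization metrics undefined")
        return {"mean_iou": None, "onset_mae_s": None, "offset_mae_s": None,
                "n_pairs": 0}
    ious = [v for _, _, v in ms.pairs]
    onset = [abs(g.onset_s - p.onset_s) for g, p, _ in ms.pairs]
    offset = [abs(g.offset_s - p.offset_s) for g, p, _ in ms.pairs]
    return {"mean_iou": float(np.mean(ious)),
            "onset_mae_s": float(np.mean(onset)),
            "offset_mae_s": float(np.mean(offset)),
            "n_pairs": len(ms.pairs)}


def error_taxonomy(ms: MatchSet) -> dict:
    """Categorize event-level errors from a match set.

    Matched pairs with differing classes count as cross-class confusions;
    unmatched reference events are misses ("... as normal"), unmatched
    predictions are false events ("normal as ...").
    """
    counts = {
        "hypopnea_as_apnea": 0,
        "apnea_as_hypopnea": 0,
        "hypopnea_as_normal": 0,
        "apnea_as_normal": 0,
        "normal_as_hypopnea": 0,
        "normal_as_apnea": 0,
        "correct": 0,
    }
    for g, p, _ in ms.pairs:
        if g.cls == p.cls:
            counts["correct"] += 1
        elif g.cls == HYPOPNEA and p.cls == APNEA:
            counts["hypopnea_as_apnea"] += 1
        elif g.cls == APNEA and p.cls == HYPOPNEA:
            counts["apnea_as_hypopnea"] += 1
    for g in ms.unmatched_gt:
        counts["hypopnea_as_normal" if g.cls == HYPOPNEA else "apnea_as_normal"] += 1
    for p in ms.unmatched_pred:
        counts["normal_as_hypopnea" if p.cls == HYPOPNEA else "normal_as_apnea"] += 1
    return counts


# ---------------------------------------------------------------------------
# frame-level
# ---------------------------------------------------------------------------

@dataclass
class FrameReport:
    confusion: np.ndarray  # (C, C), rows = truth
    precision: list[float | None]
    recall: list[float | None]
    f1: list[float | None]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float


def macro_average(values: list[float | None]) -> float:
    """Unweighted mean over classes, ignoring undefined (None) entries."""
    present = [v for v in values if v is not None]
    if not present:
        raise ValueError("no defined class metrics to average")
    return float(np.mean(present))


def frame_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  n_classes: int = 3) -> FrameReport:
    """Per-class and macro precision/recall/F1 plus overall accuracy.

    Metrics with zero denominators are reported as None (missing) and
    excluded from macro averages rather than silently counted as zero.
    """
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    precision, recall, f1 = [], [], []
    for c in range(n_classes):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else None
        r = tp / (tp + fn) if tp + fn > 0 else None
        if tp + fp + fn == 0:
            # class absent from truth and prediction: excluded, not zero
            f = None
        elif tp == 0:
            # class occurs but is never correctly retrieved
            f = 0.0
        else:
            f = 2 * p * r / (p + r)
        precision.append(p)
        recall.append(r)
        f1.append(f)
    return FrameReport(
        confusion=cm,
        precision=precision, recall=recall, f1=f1,
        macro_precision=macro_average(precision),
        macro_recall=macro_average(recall),
        macro_f1=macro_average(f1),
        accuracy=float(np.trace(cm) / cm.sum()),
    )


# ---------------------------------------------------------------------------
# patient-level
# ---------------------------------------------------------------------------

@dataclass
class PatientSummary:
    ahi: float
    ai: float
    hi: float
    n_apneas: int
    n_hypopneas: int
    sleep_hours: float


def patient_indices(ev: EventList, sleep_hours: float) -> PatientSummary:
    """AHI / AI / HI in events per hour of sleep."""
    if sleep_hours <= 0:
        raise ValueError("sleep_hours must be positive")
    n_a = len(ev.of_class(APNEA))
    n_h = len(ev.of_class(HYPOPNEA))
    return PatientSummary(
        ahi=(n_a + n_h) / sleep_hours,
        ai=n_a / sleep_hours,
        hi=n_h / sleep_hours,
        n_apneas=n_a, n_hypopneas=n_h, sleep_hours=sleep_hours,
    )


@dataclass
class AgreementReport:
    pearson_r: float | None
    mae: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def agreement_stats(audio_ahi, psg_ahi) -> AgreementReport:
    """Pearson r, MAE and Bland-Altman limits of agreement (audio - psg)."""
    audio = np.asarray(audio_ahi, dtype=np.float64)
    psg = np.asarray(psg_ahi, dtype=np.float64)
    if audio.shape != psg.shape or audio.ndim != 1 or len(audio) < 3:
        raise ValueError("need two equal-length series with n >= 3")
    d = audio - psg
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if audio.std() < 1e-12 or psg.std() < 1e-12:
        warnings.warn("zero variance; Pearson r undefined")
        r = None
    else:
        r = float(stats.pearsonr(audio, psg).statistic)
    return AgreementReport(
        pearson_r=r,
        mae=float(np.abs(d).mean()),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(audio),
    )


def mann_whitney_auc(scores, labels) -> float | None:
    """AUC as the normalized Mann-Whitney U statistic (half-credit ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def cohen_kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Chance-corrected binary agreement from confusion counts."""
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


@dataclass
class ScreeningReport:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    ppv: float | None
    npv: float | None
    kappa: float
    auc: float | None
    ci: dict = field(default_factory=dict)  # metric -> (low, high) in %


def screening_report(audio_ahi, psg_ahi, threshold: float,
                     bootstrap: bool = False, n_boot: int = 1000,
                     seed: int = 0) -> ScreeningReport:
    """Binary screening statistics at one AHI threshold (percent scale).

    Reference labels are psg_ahi >= threshold; predictions audio_ahi >=
    threshold; the AUC treats audio_ahi as a continuous score. With
    ``bootstrap=True``, percentile bootstrap CIs are attached, replaced by
    exact Clopper-Pearson intervals for proportions at 0% or 100%.
    """
    audio = np.asarray(audio_ahi, dtype=np.float64)
    psg = np.asarray(psg_ahi, dtype=np.float64)
    y = psg >= threshold
    yhat = audio >= threshold
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    tn = int(np.sum(~y & ~yhat))
    n = tp + fp + fn + tn

    def ratio(a, b):
        return 100.0 * a / b if b > 0 else None

    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("single-class reference labels; sensitivity or specificity undefined")
    rep = ScreeningReport(
        threshold=threshold, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        accuracy=100.0 * (tp + tn) / n,
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        kappa=cohen_kappa(tp, fp, fn, tn),
        auc=mann_whitney_auc(audio, y),
    )
    if bootstrap:
        rep.ci = _screening_cis(audio, psg, threshold, n_boot=n_boot, seed=seed)
        # exact intervals for degenerate proportions
        for metric, (x, m) in {
            "sensitivity": (tp, tp + fn), "specificity": (tn, tn + fp),
            "ppv": (tp, tp + fp), "npv": (tn, tn + fn),
        }.items():
            if m > 0 and x in (0, m):
                rep.ci[metric] = clopper_pearson(x, m)
    return rep


def _screening_cis(audio, psg, threshold, n_boot: int, seed: int) -> dict:
    metrics = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "kappa", "auc")

    def stat(a, p):
        r = screening_report(a, p, threshold)
        return {m: getattr(r, m) for m in metrics}

    out = {}
    samples = bootstrap_ci(stat, audio, psg, n_boot=n_boot, seed=seed)
    for m in metrics:
        if samples.get(m) is not None:
            out[m] = samples[m]
    return out


def bootstrap_ci(statistic, *series, n_boot: int = 1000, level: float = 95.0,
                 seed: int = 0):
    """Percentile bootstrap over subjects (paired resampling).

    ``statistic(*resampled_series)`` may return a float or a dict of
    floats/None. Resamples where a statistic is undefined are dropped; if
    more than 10% are dropped for a metric a warning is issued.
    """
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(s) for s in series]
    n = len(arrays[0])
    first = statistic(*arrays)
    scalar = not isinstance(first, dict)
    keys = ["value"] if scalar else list(first.keys())
    draws: dict[str, list[float]] = {k: [] for k in keys}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = statistic(*[a[idx] for a in arrays])
        except (ValueError, ZeroDivisionError):
            continue
        val = {"value": val} if scalar else val
        for k in keys:
            if val.get(k) is not None:
                draws[k].append(float(val[k]))
    lo_q, hi_q = (100 - level) / 2, 100 - (100 - level) / 2
    out = {}
    for k in keys:
        if len(draws[k]) < 0.9 * n_boot:
            warnings.warn(f"statistic {k!r} undefined on >10% of bootstrap resamples")
        if not draws[k]:
            out[k] = None
            continue
        arr = np.asarray(draws[k])
        out[k] = (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q)))
    return out["value"] if scalar else out


def clopper_pearson(successes: int, trials: int, level: float = 95.0) -> tuple[float, float]:
    """Exact binomial confidence interval on the percent scale."""
    if trials == 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials,
                                   alpha=1 - level / 100.0, method="beta")
    return 100.0 * float(low), 100.0 * float(high)
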