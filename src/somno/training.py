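"""Optimization loop: AdamW, gradient clipping, plateau LR schedule,
early stopping on validation macro-F1.

The training stream applies SpecAugment + gain perturbation online with
per-(epoch, window) derived seeds; validation windows are never
augmented. All randomness flows from TrainConfig.seed, so two runs with
the same seed produce identical histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _nn as nn
from .config import AugmentConfig, LossConfig, TrainConfig
from .evaluation import frame_metrics
from .losses import hybrid_loss_grad
from .model import DualStreamCRNN, softmax
from .signal_features import SegmentFeatures, augment

#: one labeled training example: features plus per-output-frame labels
Example = tuple[SegmentFeatures, np.ndarray]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_f1(self) -> float:
        return self.val_macro_f1[self.best_epoch]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack(examples: list[Example], aug_cfg: AugmentConfig | None,
           seeds: list[int] | None):
    feats = []
    labels = []
    for j, (feat, lab) in enumerate(examples):
        if aug_cfg is not None:
            feat = augment(feat, aug_cfg, seeds[j])
        feats.append(feat)
        labels.append(lab)
    mel = np.stack([f.mel for f in feats])
    energy = np.stack([f.energy for f in feats])
    return mel, energy, np.stack(labels)


def evaluate_frames(model: DualStreamCRNN, examples: list[Example],
                    batch_size: int = 4):
    """Eval-mode frame metrics over a labeled window set."""
    model.eval()
    preds, truths = [], []
    for i in range(0, len(examples), batch_size):
        chunk = examples[i:i + batch_size]
        mel, energy, labels = _stack(chunk, None, None)
        logits = model.forward(mel, energy)
        preds.append(np.argmax(logits, axis=-1).ravel())
        truths.append(labels.ravel())
    return frame_metrics(np.concatenate(truths), np.concatenate(preds))


def train(model: DualStreamCRNN, train_set: list[Example],
          val_set: list[Example], tcfg: TrainConfig, lcfg: LossConfig,
          aug_cfg: AugmentConfig | None = None,
          log=None) -> tuple[DualStreamCRNN, TrainHistory]:
    """Train in place; returns the best-validation model and the history."""
    if not train_set:
        raise ValueError("empty training dataset")
    if not val_set:
        raise ValueError("empty validation dataset")

    opt = nn.AdamW(model.named_parameters(), lr=tcfg.lr,
                   weight_decay=tcfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=tcfg.scheduler_factor,
                                 patience=tcfg.scheduler_patience, mode="max")
    rng = np.random.default_rng(tcfg.seed)
    history = TrainHistory()
    best_f1 = -np.inf
    best_params = None
    epochs_since_best = 0

    for epoch in range(tcfg.max_epochs):
        model.train()
        losses = []
        for step, idx in enumerate(_batches(len(train_set), tcfg.batch_size, rng)):
            examples = [train_set[i] for i in idx]
            seeds = [int(rng.integers(0, 2**31)) for _ in idx]
            mel, energy, labels = _stack(examples, aug_cfg, seeds)
            model.seed_dropout(int(rng.integers(0, 2**31)))
            model.zero_grad()
            logits = model.forward(mel, energy)
            loss, dlogits = hybrid_loss_grad(logits, labels, lcfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}"
                )
            model.backward(dlogits)
            grads = model.named_grads()
            gnorm = nn.clip_grad_norm(grads, tcfg.clip_norm)
            opt.step(grads)
            losses.append(loss)
            history.grad_norms.append(gnorm)

        val_report = evaluate_frames(model, val_set, batch_size=tcfg.batch_size)
        val_f1 = val_report.macro_f1
        history.train_loss.append(float(np.mean(losses)))
        history.val_macro_f1.append(float(val_f1))
        history.lr.append(opt.lr)
        if log is not None:
            log({"epoch": epoch, "train_loss": history.train_loss[-1],
                 "val_macro_f1": float(val_f1), "lr": opt.lr})

        # ties keep the later (longer-trained) model: with few steps per
        # epoch the eval-mode argmax can plateau while the loss still falls
        if val_f1 >= best_f1:
            if best_params is None or val_f1 > best_f1:
                epochs_since_best = 0
            else:
                epochs_since_best += 1
            best_f1 = val_f1
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.named_parameters().items()}
            best_bn = _bn_state(model)
        else:
            epochs_since_best += 1
        if epochs_since_best >= tcfg.early_stop_patience:
            break
        sched.step(float(val_f1))

    if best_params is not None:
        params = model.named_parameters()
        for k, v in best_params.items():
            params[k][...] = v
        _restore_bn(model, best_bn)
    model.eval()
    return model, history


def _bn_state(model: DualStreamCRNN):
    out = {}
    for i in range(1, len(model.blocks) + 1):
        bn = getattr(model, f"bn{i}")
        out[i] = (bn.running_mean.copy(), bn.running_var.copy())
    return out


def _restore_bn(model: DualStreamCRNN, state) -> None:
    for i, (mean, var) in state.items():
        bn = getattr(model, f"bn{i}")
        bn.running_mean[...] = mean
        bn.running_var[...] = var


def predict_labels(model: DualStreamCRNN, feats: list[SegmentFeatures],
                   batch_size: int = 4) -> list[np.ndarray]:
    """Eval-mode per-window probabilities (thin wrapper)."""
    return model.predict_proba(feats, batch_size=batch_size)


def probs_from_logits(logits: np.ndarray) -> np.ndarray:
    return softmax(logits)
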