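"""Hybrid frame-classification loss: weighted focal + soft dice.

``L_total = L_focal + lambda * L_dice`` with focusing parameter
gamma = 2, class weights alpha = (1, 4, 2) for (normal, hypopnea,
apnea) and lambda = 0.5. The focal term is the frame-mean of
``-alpha_y (1 - p_y)^gamma log(p_y)``; the dice term is the class-mean
of ``1 - (2 <p, g> + eps) / (sum p + sum g + eps)`` computed on soft
probabilities against one-hot targets.
"""

from __future__ import annotations

import numpy as np

from .config import LossConfig

_CLAMP = 1e-8


def _prep(probs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64).reshape(-1, np.shape(probs)[-1])
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels disagree in frame count")
    return probs, labels


def focal_loss(probs: np.ndarray, labels: np.ndarray, cfg: LossConfig) -> float:
    """Mean weighted focal loss over frames."""
    probs, labels = _prep(probs, labels)
    alpha = np.asarray(cfg.alpha)[labels]
    p_true = np.clip(probs[np.arange(len(labels)), labels], _CLAMP, 1.0)
    terms = -alpha * (1 - p_true) ** cfg.gamma * np.log(p_true)
    return float(terms.mean())


def dice_loss(probs: np.ndarray, labels: np.ndarray, cfg: LossConfig) -> float:
    """Soft dice loss averaged over classes (one-hot targets)."""
    probs, labels = _prep(probs, labels)
    n_classes = probs.shape[1]
    onehot = np.eye(n_classes)[labels]
    inter = (probs * onehot).sum(axis=0)
    denom = probs.sum(axis=0) + onehot.sum(axis=0)
    dice = (2 * inter + cfg.dice_smooth) / (denom + cfg.dice_smooth)
    return float((1 - dice).mean())


def hybrid_loss(probs: np.ndarray, labels: np.ndarray, cfg: LossConfig) -> float:
    return focal_loss(probs, labels, cfg) + cfg.lam * dice_loss(probs, labels, cfg)


# ---------------------------------------------------------------------------
# loss + gradient with respect to logits (used by the training loop)
# ---------------------------------------------------------------------------

def hybrid_loss_grad(logits: np.ndarray, labels: np.ndarray,
                     cfg: LossConfig) -> tuple[float, np.ndarray]:
    """Hybrid loss and its gradient w.r.t. the logits.

    `logits` may have any leading shape ending in n_classes; the returned
    gradient matches it. The loss is normalized exactly as the forward
    functions above (focal: mean over frames; dice: mean over classes).
    """
    shape = np.shape(logits)
    z = np.asarray(logits, dtype=np.float64).reshape(-1, shape[-1])
    labels_flat = np.asarray(labels, dtype=np.int64).reshape(-1)
    n, c = z.shape

    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    probs = e / e.sum(axis=1, keepdims=True)

    # ----- focal -----
    idx = np.arange(n)
    alpha = np.asarray(cfg.alpha)[labels_flat]
    p_raw = probs[idx, labels_flat]
    p_true = np.clip(p_raw, _CLAMP, 1.0)
    one_m = 1 - p_true
    focal = float((-alpha * one_m ** cfg.gamma * np.log(p_true)).mean())
    # dL/dp_y per frame (0 where clamped below)
    if cfg.gamma == 0:
        dldp = -alpha / p_true
    else:
        dldp = -alpha * (-cfg.gamma * one_m ** (cfg.gamma - 1) * np.log(p_true)
                         + one_m ** cfg.gamma / p_true)
    dldp = np.where(p_raw < _CLAMP, 0.0, dldp) / n
    dfocal_dp = np.zeros_like(probs)
    dfocal_dp[idx, labels_flat] = dldp

    # ----- dice -----
    onehot = np.eye(c)[labels_flat]
    inter = (probs * onehot).sum(axis=0)
    sum_p = probs.sum(axis=0)
    sum_g = onehot.sum(axis=0)
    num = 2 * inter + cfg.dice_smooth
    den = sum_p + sum_g + cfg.dice_smooth
    dice = float((1 - num / den).mean())
    # d(1 - num/den)/dp_tc = -(2 g_tc * den_c - num_c) / den_c^2, / C for the mean
    ddice_dp = -(2 * onehot * den - num) / (den ** 2) / c

    dl_dp = dfocal_dp + cfg.lam * ddice_dp
    # softmax backward: dz = p * (dl_dp - sum_c dl_dp * p)
    dz = probs * (dl_dp - (dl_dp * probs).sum(axis=1, keepdims=True))
    loss = focal + cfg.lam * dice
    return loss, dz.reshape(shape).astype(np.float32)
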