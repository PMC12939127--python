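"""AdamW optimizer, global-norm gradient clipping, plateau LR scheduler."""

from __future__ import annotations

import numpy as np


def clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is <= max_norm.

    Returns the pre-clip global norm.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                              for g in grads.values())))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p *= 1 - self.lr * self.weight_decay
            p -= (self.lr * (self.m[k] / bc1)
                  / (np.sqrt(self.v[k] / bc2) + self.eps)).astype(p.dtype)


class ReduceLROnPlateau:
    """Halve (by `factor`) the LR when the monitored metric plateaus.

    `mode='max'`: a metric that fails to improve for `patience` consecutive
    epochs triggers a reduction.
    """

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 2,
                 mode: str = "max", min_lr: float = 1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.min_lr = min_lr
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Report one epoch's metric; returns True if the LR was reduced."""
        if self.sign * metric > self.best:
            self.best = self.sign * metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience - 1 and self.patience > 0:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
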