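"""Dual-stream convolutional-recurrent frame classifier.

Spectral stream: four VGG-style conv blocks (3x3 conv, batch-norm, ReLU,
max-pool) over the 128 x 6000 log-mel matrix, pooling 2x2 in the first
three blocks and 2x1 (frequency only) in the last so that the output
keeps one frame per 80 ms. A squeeze-and-excitation gate recalibrates
the 256 channels, and the (256, 8) channel-frequency slab at each frame
is flattened to 2048 features.

Energy stream: the 6000-sample energy curve is mean-pooled onto the
750-frame grid and lifted to 64 dimensions by a per-frame MLP with
layer normalization.

The concatenated 2112-dim frame vectors are projected to 256, passed
through a 2-layer bidirectional LSTM (128 hidden per direction) and a
time-distributed linear head producing 3-class logits per frame. With
the default configuration the network has exactly 1,734,147 trainable
parameters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import _nn as nn
from .config import ModelConfig, RunConfig
from .signal_features import SegmentFeatures


class DualStreamCRNN(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        flatten = cfg.flatten_dim  # raises if pooling does not divide n_mels
        if cfg.n_mels % cfg.freq_pool_total:
            raise ValueError("n_mels must be divisible by the pooling schedule")

        chans = (1,) + tuple(cfg.conv_channels)
        self.blocks: list[tuple[nn.Conv2d, nn.BatchNorm2d, nn.ReLU, nn.MaxPool2d]] = []
        for i, pool in enumerate(cfg.pool_schedule):
            conv = nn.Conv2d(chans[i], chans[i + 1], rng)
            bn = nn.BatchNorm2d(chans[i + 1])
            relu = nn.ReLU()
            mp = nn.MaxPool2d(tuple(pool))
            # register as attributes so parameter traversal sees them
            setattr(self, f"conv{i + 1}", conv)
            setattr(self, f"bn{i + 1}", bn)
            setattr(self, f"relu{i + 1}", relu)
            setattr(self, f"pool{i + 1}", mp)
            self.blocks.append((conv, bn, relu, mp))

        self.se = nn.SEBlock(cfg.conv_channels[-1], cfg.se_reduction, rng,
                             bias=cfg.se_bias)

        self.energy_fc1 = nn.Linear(1, cfg.energy_hidden, rng)
        self.energy_relu = nn.ReLU()
        self.energy_fc2 = nn.Linear(cfg.energy_hidden, cfg.energy_hidden, rng)
        self.energy_ln = nn.LayerNorm(cfg.energy_hidden)

        self.fusion = nn.Linear(flatten + cfg.energy_hidden, cfg.fusion_dim, rng)
        self.fusion_ln = nn.LayerNorm(cfg.fusion_dim)

        lstm_out = cfg.lstm_hidden * (2 if cfg.bidirectional else 1)
        if lstm_out != cfg.fusion_dim:
            raise ValueError("LSTM output width must equal fusion_dim")
        self.lstm = nn.LSTM(cfg.fusion_dim, cfg.lstm_hidden, cfg.lstm_layers,
                            rng, bidirectional=cfg.bidirectional,
                            dropout=cfg.dropout)
        self.head_dropout = nn.Dropout(cfg.dropout)
        self.classifier = nn.Linear(lstm_out, cfg.n_classes, rng)

        self._pool = None  # adaptive pool instantiated per input length
        self._shapes = None

    def seed_dropout(self, seed: int) -> None:
        """Reseed the stochastic (dropout) streams for a reproducible step."""
        self.lstm.rng = np.random.default_rng(seed)
        self.head_dropout.rng = np.random.default_rng(seed + 1)

    # ------------------------------------------------------------------
    def forward(self, mel: np.ndarray, energy: np.ndarray) -> np.ndarray:
        """(B, n_mels, T_in), (B, T_in) -> logits (B, Tseq, n_classes)."""
        mel = np.asarray(mel, dtype=np.float32)
        energy = np.asarray(energy, dtype=np.float32)
        if mel.ndim == 2:
            mel, energy = mel[None], energy[None]
        b, n_mels, t_in = mel.shape
        if n_mels != self.cfg.n_mels:
            raise ValueError(f"expected {self.cfg.n_mels} mel bands, got {n_mels}")
        if energy.shape != (b, t_in):
            raise ValueError(
                f"energy shape {energy.shape} does not match mel frames ({b}, {t_in})"
            )
        if t_in % self.cfg.time_pool_total:
            raise ValueError("input frame count must be divisible by the time pooling")
        t_seq = t_in // self.cfg.time_pool_total

        x = mel[:, None]  # (B, 1, F, T)
        for conv, bn, relu, mp in self.blocks:
            x = mp(relu(bn(conv(x))))
        x = self.se(x)
        bb, c, f, t = x.shape
        # (B, C, F, T) -> (B, T, C*F) frame-major flatten
        feat = x.transpose(0, 3, 1, 2).reshape(bb, t, c * f)

        self._pool = nn.AdaptiveAvgPool1d(t_seq)
        e = self._pool(energy)[:, :, None]  # (B, Tseq, 1)
        e = self.energy_ln(self.energy_fc2(self.energy_relu(self.energy_fc1(e))))

        fused = self.fusion_ln(self.fusion(np.concatenate([feat, e], axis=-1)))
        out = self.lstm(fused)
        out = self.head_dropout(out)
        logits = self.classifier(out)
        self._shapes = (bb, c, f, t)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        bb, c, f, t = self._shapes
        d = self.classifier.backward(dlogits)
        d = self.head_dropout.backward(d)
        d = self.lstm.backward(d)
        d = self.fusion_ln.backward(d)
        d = self.fusion.backward(d)
        dfeat = d[:, :, :c * f]
        de = d[:, :, c * f:]
        de = self.energy_ln.backward(de)
        de = self.energy_fc1.backward(
            self.energy_relu.backward(self.energy_fc2.backward(de)))
        _ = self._pool.backward(de[:, :, 0])  # energy input needs no grad
        dx = dfeat.reshape(bb, t, c, f).transpose(0, 2, 3, 1)
        dx = self.se.backward(np.ascontiguousarray(dx, dtype=np.float32))
        for conv, bn, relu, mp in reversed(self.blocks):
            dx = conv.backward(bn.backward(relu.backward(mp.backward(dx))))

    # ------------------------------------------------------------------
    def predict_proba(self, feats: list[SegmentFeatures] | SegmentFeatures,
                      batch_size: int = 4) -> list[np.ndarray]:
        """Eval-mode softmax probabilities per window, each (Tseq, 3)."""
        single = isinstance(feats, SegmentFeatures)
        if single:
            feats = [feats]
        self.eval()
        out = []
        for i in range(0, len(feats), batch_size):
            chunk = feats[i:i + batch_size]
            mel = np.stack([f.mel for f in chunk])
            en = np.stack([f.energy for f in chunk])
            logits = self.forward(mel, en)
            out.extend(softmax(l) for l in logits)
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> DualStreamCRNN:
    """Instantiate the dual-stream CRNN (validates the flatten invariant)."""
    cfg = cfg or ModelConfig()
    return DualStreamCRNN(cfg, rng=np.random.default_rng(seed))


def count_parameters(model: nn.Module) -> int:
    """Total size of trainable tensors (batch-norm running stats excluded)."""
    return model.n_parameters()


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: DualStreamCRNN, run_cfg: RunConfig, path) -> None:
    """Write weights (.npz) plus a YAML sidecar with config and hash."""
    path = Path(path).with_suffix(".npz")
    params = model.named_parameters()
    arrays = dict(params)
    # persist batch-norm running statistics alongside (not trainable)
    for i in range(1, len(model.blocks) + 1):
        bn = getattr(model, f"bn{i}")
        arrays[f"bn{i}.running_mean"] = bn.running_mean
        arrays[f"bn{i}.running_var"] = bn.running_var
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"config": run_cfg.to_dict(),
                        "config_hash": run_cfg.config_hash()}, fh)


def load_checkpoint(path, run_cfg: RunConfig | None = None) -> tuple[DualStreamCRNN, RunConfig]:
    path = Path(path).with_suffix(".npz")
    with open(path.with_suffix(".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    stored_cfg = RunConfig.from_dict(sidecar["config"])
    if run_cfg is not None and run_cfg.config_hash() != sidecar["config_hash"]:
        raise ValueError("checkpoint config hash does not match the requested config")
    model = build_model(stored_cfg.model)
    data = np.load(path)
    params = model.named_parameters()
    for name, arr in params.items():
        arr[...] = data[name]
    for i in range(1, len(model.blocks) + 1):
        bn = getattr(model, f"bn{i}")
        bn.running_mean[...] = data[f"bn{i}.running_mean"]
        bn.running_var[...] = data[f"bn{i}.running_var"]
    return model, stored_cfg
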