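"""Configuration objects for every stage of the pipeline.

Each config is a plain dataclass with defaults matching the reference
operating point of the detector: 16 kHz audio, 60 s windows with 30 s
stride, 128-band log-mel features at 10 ms hop, an 80 ms output frame
grid, and the clinically constrained post-processing rules (median
kernel 5, <3 s gap merging, >=10 s minimum event duration).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml


@dataclass
class FeatureConfig:
    """Front-end parameters for log-mel + energy feature extraction."""

    target_rate: int = 16000
    window_s: float = 60.0
    stride_s: float = 30.0
    nfft: int = 1024
    hop: int = 160
    n_mels: int = 128
    log_floor: float = 1e-10
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    norm: str = "global"  # "global" | "per_bin" spectrogram z-normalization

    def __post_init__(self) -> None:
        if self.n_mels <= 0:
            raise ValueError("n_mels must be positive")
        if self.stride_s > self.window_s:
            raise ValueError("stride_s must not exceed window_s")
        if (round(self.window_s * self.target_rate)) % self.hop != 0:
            raise ValueError("hop must divide window_s * target_rate")
        if self.norm not in ("global", "per_bin"):
            raise ValueError("norm must be 'global' or 'per_bin'")

    @property
    def window_samples(self) -> int:
        return round(self.window_s * self.target_rate)

    @property
    def stride_samples(self) -> int:
        return round(self.stride_s * self.target_rate)

    @property
    def frames_per_window(self) -> int:
        """Number of 10 ms mel frames in one analysis window (6000)."""
        return self.window_samples // self.hop


@dataclass
class AugmentConfig:
    """SpecAugment masking plus shared-gain perturbation (training only)."""

    freq_mask_max: int = 15
    time_mask_max: int = 40
    n_freq_masks: int = 1
    n_time_masks: int = 1
    gain_low: float = 0.8
    gain_high: float = 1.2

    def __post_init__(self) -> None:
        if self.freq_mask_max < 0 or self.time_mask_max < 0:
            raise ValueError("mask widths must be non-negative")
        if self.gain_low > self.gain_high:
            raise ValueError("gain_low must not exceed gain_high")


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the dual-stream CRNN.

    The defaults pin the configuration whose trainable parameter count is
    exactly 1,734,147: four VGG-style conv blocks (32/64/128/256 channels,
    batch-norm, 2x2 pooling except 2x1 in the last block), a bias-free SE
    gate with reduction 16, a 1->64->64 energy MLP with layer-norm, a
    2112->256 fusion projection, and a 2-layer BiLSTM with 128 hidden
    units per direction.
    """

    n_mels: int = 128
    conv_channels: Sequence[int] = (32, 64, 128, 256)
    pool_schedule: Sequence[Sequence[int]] = ((2, 2), (2, 2), (2, 2), (2, 1))
    se_reduction: int = 16
    se_bias: bool = False
    energy_hidden: int = 64
    fusion_dim: int = 256
    lstm_hidden: int = 128
    lstm_layers: int = 2
    bidirectional: bool = True
    dropout: float = 0.2
    n_classes: int = 3

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.pool_schedule = tuple(tuple(int(p) for p in ps) for ps in self.pool_schedule)
        if len(self.conv_channels) != len(self.pool_schedule):
            raise ValueError("conv_channels and pool_schedule must have equal length")

    @property
    def freq_pool_total(self) -> int:
        out = 1
        for pf, _ in self.pool_schedule:
            out *= pf
        return out

    @property
    def time_pool_total(self) -> int:
        out = 1
        for _, pt in self.pool_schedule:
            out *= pt
        return out

    @property
    def flatten_dim(self) -> int:
        if self.n_mels % self.freq_pool_total:
            raise ValueError("n_mels must be divisible by the frequency pooling product")
        return (self.n_mels // self.freq_pool_total) * self.conv_channels[-1]


@dataclass
class LossConfig:
    """Hybrid focal + dice loss settings."""

    gamma: float = 2.0
    alpha: Sequence[float] = (1.0, 4.0, 2.0)  # (normal, hypopnea, apnea)
    lam: float = 0.5
    dice_smooth: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = tuple(float(a) for a in self.alpha)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("alpha weights must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class TrainConfig:
    """Optimization loop settings (AdamW + plateau scheduler)."""

    lr: float = 5e-4
    weight_decay: float = 5e-2
    scheduler_factor: float = 0.5
    scheduler_patience: int = 2
    clip_norm: float = 1.0
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")


@dataclass
class PostprocessConfig:
    """Clinical event post-processing constraints."""

    median_kernel: int = 5
    merge_gap_s: float = 3.0
    min_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.merge_gap_s < 0 or self.min_duration_s < 0:
            raise ValueError("merge_gap_s and min_duration_s must be >= 0")


@dataclass
class MatchConfig:
    """Event matching threshold for temporal IoU evaluation."""

    iou_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.iou_min <= 1:
            raise ValueError("iou_min must lie in [0, 1]")


@dataclass
class SynthConfig:
    """Synthetic full-night breathing-audio generator settings.

    Event durations follow the pooled clinical statistics of scored
    respiratory events (hypopnea 16.58 +/- 6.68 s, apnea 23.39 +/- 10.10 s),
    truncated at the 10 s clinical minimum.
    """

    seed: int = 0
    night_minutes: float = 60.0
    breath_period_s: float = 4.0
    snore_band_hz: Sequence[float] = (100.0, 2000.0)
    noise_floor_db: float = -45.0
    hypopnea_atten: Sequence[float] = (0.3, 0.7)  # uniform amplitude factor
    apnea_atten: float = 0.02
    hypopnea_dur_mean: float = 16.58
    hypopnea_dur_sd: float = 6.68
    apnea_dur_mean: float = 23.39
    apnea_dur_sd: float = 10.10
    min_duration_s: float = 10.0
    target_ahi: float = 30.0
    apnea_fraction: float = 0.6
    min_gap_s: float = 20.0
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        lo, hi = self.hypopnea_atten
        if not (0 < lo <= hi < 1):
            raise ValueError("hypopnea attenuation must lie in (0, 1)")
        if self.apnea_atten >= lo:
            raise ValueError("apnea attenuation must be below hypopnea attenuation")
        if self.min_duration_s < 0:
            raise ValueError("min_duration_s must be >= 0")


FRAME_PERIOD_S = 0.08  # model output resolution: 80 ms per frame


@dataclass
class RunConfig:
    """Bundle of all stage configs plus the master seed."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        sections = {
            "features": FeatureConfig,
            "augment": AugmentConfig,
            "model": ModelConfig,
            "loss": LossConfig,
            "train": TrainConfig,
            "postprocess": PostprocessConfig,
            "match": MatchConfig,
            "synth": SynthConfig,
        }
        for key, typ in sections.items():
            if key in d and d[key] is not None:
                kwargs[key] = typ(**d[key])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
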