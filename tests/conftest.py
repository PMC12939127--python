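import numpy as np
import pytest

from somno.config import (AugmentConfig, FeatureConfig, LossConfig,
                          ModelConfig, PostprocessConfig, RunConfig)


@pytest.fixture(scope="session")
def feature_cfg():
    return FeatureConfig()


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Scaled-down architecture (same family) for fast gradient/training tests."""
    return ModelConfig(
        n_mels=16, conv_channels=(4, 8, 8, 8),
        pool_schedule=((2, 2), (2, 2), (2, 2), (2, 1)),
        se_reduction=4, energy_hidden=6, fusion_dim=16, lstm_hidden=8,
        lstm_layers=2, dropout=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def segment_60s():
    """One 60 s synthetic audio segment at 16 kHz (breathing-like)."""
    r = np.random.default_rng(7)
    sr = 16000
    t = np.arange(60 * sr) / sr
    env = np.clip(np.sin(2 * np.pi * t / 4.0), 0, None) ** 2
    return (env * r.standard_normal(60 * sr) * 0.3).astype(np.float64)
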