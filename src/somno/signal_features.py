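"""Audio front end: resampling, windowing, log-mel + energy features.

The feature pipeline mirrors a standard mel front end: band-limited
polyphase resampling to 16 kHz, 60 s analysis windows with 30 s stride,
a centered Hann STFT (NFFT 1024, hop 160 -> 10 ms frames), a 128-band
Slaney mel filterbank up to Nyquist, and decibel scaling
``10*log10(power + 1e-10)``. Each 60 s window yields a 128 x 6000 matrix.
The auxiliary energy profile is the across-band mean of the (raw) log-mel
matrix; matrix and curve are then z-normalized independently per segment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly
from scipy.signal.windows import hann

from .config import AugmentConfig, FeatureConfig


@dataclass
class AudioRecording:
    """Mono audio samples at a known rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # stereo -> channel mean
            self.samples = self.samples.mean(axis=1)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class SegmentFeatures:
    """Normalized features for one analysis window."""

    mel: np.ndarray  # (n_mels, T_in)
    energy: np.ndarray  # (T_in,)
    start_s: float
    padded_frames: int = 0  # trailing frames that are zero-padding (inference)

    @property
    def n_frames(self) -> int:
        return self.mel.shape[1]


def load_wav(path) -> AudioRecording:
    """Read a PCM/float WAV file; integer formats are scaled to [-1, 1]."""
    rate, data = wavfile.read(Path(path))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return AudioRecording(samples=data, sample_rate=rate)


def save_wav(rec: AudioRecording, path) -> None:
    wavfile.write(Path(path), rec.sample_rate, rec.samples.astype(np.float32))


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Band-limited polyphase resampling to ``target_rate``."""
    if len(rec.samples) == 0:
        raise ValueError("empty recording")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rec.sample_rate == target_rate:
        return AudioRecording(rec.samples.copy(), target_rate)
    frac = Fraction(target_rate, rec.sample_rate)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_out = round(len(rec.samples) * target_rate / rec.sample_rate)
    if len(out) > n_out:
        out = out[:n_out]
    elif len(out) < n_out:
        out = np.pad(out, (0, n_out - len(out)))
    return AudioRecording(out, target_rate)


def segment_windows(rec: AudioRecording, cfg: FeatureConfig,
                    inference: bool = False) -> list[tuple[float, slice, int]]:
    """Plan analysis windows as ``(start_s, sample_slice, pad_samples)``.

    Training mode keeps only complete windows (start at 0, stride_s, ...).
    Inference mode appends one final zero-padded window when a trailing
    remainder is left uncovered, flagged via ``pad_samples > 0``.
    """
    if rec.sample_rate != cfg.target_rate:
        raise ValueError(
            f"recording rate {rec.sample_rate} != target rate {cfg.target_rate}; resample first"
        )
    n = len(rec.samples)
    win = cfg.window_samples
    stride = cfg.stride_samples
    out: list[tuple[float, slice, int]] = []
    if n < win:
        if not inference:
            warnings.warn("recording shorter than one window; no training windows")
            return out
        return [(0.0, slice(0, n), win - n)] if n else out
    n_full = (n - win) // stride + 1
    for i in range(n_full):
        s0 = i * stride
        out.append((s0 / cfg.target_rate, slice(s0, s0 + win), 0))
    if inference:
        covered = (n_full - 1) * stride + win
        if covered < n:
            s0 = n_full * stride
            out.append((s0 / cfg.target_rate, slice(s0, n), win - (n - s0)))
    return out


def mel_filterbank(sr: int, nfft: int, n_mels: int, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Slaney-style triangular mel filterbank, shape (n_mels, nfft//2 + 1).

    Linear below 1 kHz (step 200/3 Hz per mel), logarithmic above, with
    each triangle area-normalized by 2 / bandwidth (Slaney norm).
    """
    if fmax is None:
        fmax = sr / 2.0

    def hz_to_mel(f):
        f = np.asarray(f, dtype=np.float64)
        f_sp = 200.0 / 3.0
        mel = f / f_sp
        min_log_hz = 1000.0
        min_log_mel = min_log_hz / f_sp
        logstep = math.log(6.4) / 27.0
        above = f >= min_log_hz
        mel = np.where(above, min_log_mel + np.log(np.maximum(f, min_log_hz) / min_log_hz) / logstep, mel)
        return mel

    def mel_to_hz(m):
        m = np.asarray(m, dtype=np.float64)
        f_sp = 200.0 / 3.0
        hz = m * f_sp
        min_log_hz = 1000.0
        min_log_mel = min_log_hz / f_sp
        logstep = math.log(6.4) / 27.0
        above = m >= min_log_mel
        hz = np.where(above, min_log_hz * np.exp(logstep * (np.maximum(m, min_log_mel) - min_log_mel)), hz)
        return hz

    fft_freqs = np.linspace(0.0, sr / 2.0, nfft // 2 + 1)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)

    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # Slaney area normalization
    return fb


def _stft_power(x: np.ndarray, nfft: int, hop: int) -> np.ndarray:
    """Centered Hann power STFT with frame count trimmed to len(x)//hop.

    Frame i is centered at i*hop so it represents [i*hop, (i+1)*hop) s of
    signal on the 10 ms grid.
    """
    if len(x) < nfft:
        raise ValueError(f"segment ({len(x)} samples) shorter than NFFT ({nfft})")
    n_frames = len(x) // hop
    pad = nfft // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    idx = np.arange(nfft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * hann(nfft, sym=False)[None, :]
    spectrum = np.fft.rfft(frames, n=nfft, axis=1)
    return (spectrum.real**2 + spectrum.imag**2).T  # (nfft//2+1, n_frames)


def logmel(samples: np.ndarray, cfg: FeatureConfig,
           fb: np.ndarray | None = None) -> np.ndarray:
    """Log-mel spectrogram of a segment, shape (n_mels, len(samples)//hop)."""
    samples = np.asarray(samples, dtype=np.float64)
    power = _stft_power(samples, cfg.nfft, cfg.hop)
    if fb is None:
        fb = mel_filterbank(cfg.target_rate, cfg.nfft, cfg.n_mels, cfg.fmin, cfg.fmax)
    melspec = fb @ power
    return 10.0 * np.log10(melspec + cfg.log_floor)


def energy_profile(mel_matrix: np.ndarray) -> np.ndarray:
    """Across-band mean intensity per time step of a (raw) log-mel matrix."""
    return np.asarray(mel_matrix, dtype=np.float64).mean(axis=0)


def znormalize(values: np.ndarray, axis=None) -> np.ndarray:
    """Zero-mean unit-variance scaling (population std); constant -> zeros."""
    values = np.asarray(values, dtype=np.float64)
    mean = values.mean(axis=axis, keepdims=axis is not None)
    std = values.std(axis=axis, keepdims=axis is not None)
    out = values - mean
    safe = np.where(std < 1e-8, 1.0, std)
    out = out / safe
    if axis is None:
        if std < 1e-8:
            out[:] = 0.0
    else:
        out = np.where(std < 1e-8, 0.0, out)
    return out


def extract_features(samples: np.ndarray, cfg: FeatureConfig, start_s: float = 0.0,
                     padded_frames: int = 0,
                     fb: np.ndarray | None = None) -> SegmentFeatures:
    """Full per-segment front end: log-mel, energy, independent z-norms."""
    mel_raw = logmel(samples, cfg, fb=fb)
    energy = energy_profile(mel_raw)  # from the raw log-mel, pre-normalization
    if cfg.norm == "per_bin":
        mel = znormalize(mel_raw, axis=1)
    else:
        mel = znormalize(mel_raw)
    return SegmentFeatures(
        mel=mel.astype(np.float32),
        energy=znormalize(energy).astype(np.float32),
        start_s=start_s,
        padded_frames=padded_frames,
    )


def featurize_recording(rec: AudioRecording, cfg: FeatureConfig,
                        inference: bool = True) -> list[SegmentFeatures]:
    """Resample (if needed), window and featurize a whole recording."""
    if rec.sample_rate != cfg.target_rate:
        rec = resample(rec, cfg.target_rate)
    fb = mel_filterbank(cfg.target_rate, cfg.nfft, cfg.n_mels, cfg.fmin, cfg.fmax)
    out = []
    for start_s, span, pad in segment_windows(rec, cfg, inference=inference):
        seg = rec.samples[span]
        if pad:
            seg = np.pad(seg, (0, pad))
        out.append(
            extract_features(seg, cfg, start_s=start_s,
                             padded_frames=pad // cfg.hop, fb=fb)
        )
    return out


def spec_augment(feat: SegmentFeatures, cfg: AugmentConfig, rng_seed: int) -> SegmentFeatures:
    """SpecAugment masking on the normalized mel matrix (energy untouched).

    Mask widths are drawn uniformly from {0..max}; masked cells are set to
    0, the per-segment mean in normalized units. Deterministic per seed.
    """
    rng = np.random.default_rng(rng_seed)
    mel = feat.mel.copy()
    n_mels, t = mel.shape
    for _ in range(cfg.n_freq_masks):
        w = int(rng.integers(0, cfg.freq_mask_max + 1))
        if w:
            f0 = int(rng.integers(0, n_mels - w + 1))
            mel[f0:f0 + w, :] = 0.0
    for _ in range(cfg.n_time_masks):
        w = int(rng.integers(0, cfg.time_mask_max + 1))
        if w:
            t0 = int(rng.integers(0, t - w + 1))
            mel[:, t0:t0 + w] = 0.0
    return SegmentFeatures(mel=mel, energy=feat.energy.copy(),
                           start_s=feat.start_s, padded_frames=feat.padded_frames)


def gain_perturb(feat: SegmentFeatures, cfg: AugmentConfig, rng_seed: int) -> SegmentFeatures:
    """Multiply mel and energy by one shared gain ~ U(gain_low, gain_high)."""
    rng = np.random.default_rng(rng_seed)
    g = float(rng.uniform(cfg.gain_low, cfg.gain_high))
    return SegmentFeatures(mel=(feat.mel * g).astype(feat.mel.dtype),
                           energy=(feat.energy * g).astype(feat.energy.dtype),
                           start_s=feat.start_s, padded_frames=feat.padded_frames)


def augment(feat: SegmentFeatures, cfg: AugmentConfig, rng_seed: int) -> SegmentFeatures:
    """Training-time augmentation: masking first, then shared gain."""
    out = spec_augment(feat, cfg, rng_seed)
    return gain_perturb(out, cfg, rng_seed + 1)
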