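"""Deterministic audio preprocessing for the cough classifier.

The classifier consumes fixed-duration mono 16 kHz clips turned into linear
magnitude spectrograms.  The chain is:

1. standardize: any rate/channel/bit-depth -> mono, 16 kHz, fixed duration,
   amplitudes in [-1, 1];
2. silence gate on the *raw* (pre-normalization) amplitude — gating after
   amplitude normalization is a known failure mode, because normalization
   erases the level information the gate relies on;
3. peak normalization to [-1, 1];
4. short-time magnitude spectrum: 256-point FFT, 256-sample Hann window,
   hop 100 samples, end-padded so a 1 s clip yields exactly 129 x 160;
5. model input: bilinear resize of the time axis to 124 columns, then
   per-sample standardization to zero mean / unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, gcd

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import rfft
from scipy.io import wavfile

TARGET_RATE = 16_000
N_FREQ_BINS = 129          # one-sided bins of a 256-point FFT
MODEL_TIME_BINS = 124      # time axis after the resizing stage


class AudioFormatError(ValueError):
    """Raised for empty, non-finite or otherwise unusable audio input."""


@dataclass(frozen=True)
class FrontendConfig:
    """Spectrogram front-end parameters.

    ``nfft=256`` at 16 kHz gives 129 one-sided bins spaced 62.5 Hz; hop 100
    samples is 6.25 ms, so a 1 s clip yields ceil(16000/100) = 160 frames.
    ``silence_rms_threshold`` is a fraction of full scale.
    """

    nfft: int = 256
    window: int = 256
    hop: int = 100
    silence_rms_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.nfft < self.window:
            raise AudioFormatError("nfft must be >= window length")
        if self.hop <= 0:
            raise AudioFormatError("hop must be positive")


@dataclass
class AudioClip:
    """Fixed-duration mono 16 kHz waveform, amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate: int = TARGET_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError("clip must be mono (1-D)")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Spectrogram:
    """Linear-frequency magnitude spectrogram, 129 x T, entries >= 0."""

    magnitudes: np.ndarray
    bin_hz: float = TARGET_RATE / 256
    hop_s: float = 100 / TARGET_RATE

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.shape[0] != N_FREQ_BINS:
            raise AudioFormatError(f"expected {N_FREQ_BINS} frequency rows")
        if (self.magnitudes < 0).any():
            raise AudioFormatError("magnitudes must be non-negative")


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if np.issubdtype(samples.dtype, np.integer):
        info = np.iinfo(samples.dtype)
        scale = max(abs(info.min), info.max)
        return samples.astype(np.float64) / scale
    return samples.astype(np.float64)


def standardize_clip(samples: np.ndarray, rate: int,
                     target_duration: float = 1.0) -> AudioClip:
    """Convert arbitrary audio to the canonical clip format.

    Multichannel input is mixed down by channel mean, the result resampled
    to 16 kHz (polyphase), then right-trimmed or zero-padded to
    ``target_duration``.  Input already in canonical form passes through
    bit for bit.
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise AudioFormatError("empty audio")
    x = _to_float(samples)
    if not np.isfinite(x).any():
        raise AudioFormatError("audio contains no finite samples")
    x = np.nan_to_num(x)
    if x.ndim == 2:
        x = x.mean(axis=1)
    elif x.ndim != 1:
        raise AudioFormatError("audio must be 1-D or 2-D (frames x channels)")
    if rate != TARGET_RATE:
        g = gcd(int(rate), TARGET_RATE)
        x = signal.resample_poly(x, TARGET_RATE // g, int(rate) // g)
    n_target = int(round(target_duration * TARGET_RATE))
    if len(x) >= n_target:
        x = x[:n_target]
    else:
        x = np.pad(x, (0, n_target - len(x)))
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    return AudioClip(samples=x)


def silence_gate(clip: AudioClip, threshold: float | None = None,
                 cfg: FrontendConfig | None = None) -> bool:
    """True (silence: skip inference) iff raw RMS < threshold x full scale.

    Must be applied to the clip *before* any amplitude normalization, which
    would otherwise rescale quiet clips to full level and defeat the gate.
    Exactly-at-threshold clips are not silence (strict inequality).
    """
    if threshold is None:
        threshold = (cfg or FrontendConfig()).silence_rms_threshold
    rms = float(np.sqrt(np.mean(clip.samples ** 2)))
    return rms < threshold


def peak_normalize(clip: AudioClip) -> AudioClip:
    """Scale to peak |amplitude| 1; an all-zero clip is returned unchanged."""
    peak = np.abs(clip.samples).max()
    if peak == 0:
        return AudioClip(samples=clip.samples.copy())
    return AudioClip(samples=clip.samples / peak)


def compute_spectrogram(clip: AudioClip, cfg: FrontendConfig | None = None,
                        normalize: bool = True) -> Spectrogram:
    """One-sided magnitude short-time spectrum of the clip.

    The clip is end-padded with zeros so the frame count is exactly
    ``ceil(len / hop)`` (160 for one second); each frame is Hann-windowed
    before a 256-point real FFT.
    """
    cfg = cfg or FrontendConfig()
    x = peak_normalize(clip).samples if normalize else clip.samples
    if len(x) < cfg.window:
        raise AudioFormatError("clip shorter than one analysis window")
    n_frames = ceil(len(x) / cfg.hop)
    needed = (n_frames - 1) * cfg.hop + cfg.window
    x = np.pad(x, (0, needed - len(x)))
    idx = np.arange(cfg.window)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * signal.get_window("hann", cfg.window, fftbins=True)
    mags = np.abs(rfft(frames, n=cfg.nfft, axis=1)).T  # (129, n_frames)
    return Spectrogram(magnitudes=mags)


def _resize_time_axis(mat: np.ndarray, n_out: int) -> np.ndarray:
    """Bilinear resample of the time (column) axis, half-pixel convention
    (corner alignment off), edges clamped."""
    n_in = mat.shape[1]
    if n_in == n_out:
        return mat.copy()
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    lo = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    w = np.clip(pos - lo, 0.0, 1.0)
    return mat[:, lo] * (1.0 - w) + mat[:, hi] * w


def prepare_model_input(spec: Spectrogram, epsilon: float = 1e-6) -> np.ndarray:
    """Resize to 129 x 124 and standardize per sample.

    Mirrors the classifier's two leading layers: a resizing stage on the
    time axis, then ``(x - mean) / max(std, epsilon)`` over the whole
    matrix.  A constant spectrogram maps to all zeros.
    """
    resized = _resize_time_axis(spec.magnitudes, MODEL_TIME_BINS)
    mu = resized.mean()
    sd = resized.std()
    return (resized - mu) / max(sd, epsilon)


def clip_to_model_input(clip: AudioClip, cfg: FrontendConfig | None = None
                        ) -> np.ndarray | None:
    """Full front end for one clip; None if the silence gate fires."""
    cfg = cfg or FrontendConfig()
    if silence_gate(clip, cfg=cfg):
        return None
    return prepare_model_input(compute_spectrogram(clip, cfg))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_wav(path, target_duration: float | None = None) -> AudioClip:
    """Read a WAV file and standardize it.

    ``target_duration=None`` keeps the file's own (resampled) duration.
    """
    rate, data = wavfile.read(path)
    if target_duration is None:
        target_duration = data.shape[0] / rate
    return standardize_clip(data, rate, target_duration)


def write_wav(path, clip: AudioClip) -> None:
    """Write 16-bit PCM mono at 16 kHz (RIFF, little-endian)."""
    # Scale by 32768 (the read-side divisor) so write->read->write is the
    # identity on PCM words; exactly-full-scale +1.0 clips to 32767.
    pcm = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, clip.rate, pcm)


def spectrogram_to_csv(spec: Spectrogram, path) -> None:
    pd.DataFrame(spec.magnitudes).to_csv(path, index=False, header=False)
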