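"""Seeded synthetic audio for the five sound classes.

Stands in for the real training corpora (cough recordings, household/office
sounds, music, podcast speech, ambient room noise).  Signal models are
deliberately simple but give each class a distinct spectro-temporal
signature, with enough within-class variability and cross-class ambiguity
(the "other" class deliberately contains cough-like clicks and music-like
tone bursts) that a trained classifier is exercised meaningfully rather than
trivially:

- ``cough``    : 1-2 exponentially decaying broadband bursts (80-300 ms),
                 band-emphasized 300-3000 Hz, sharp attack;
- ``other``    : transients and tones that violate the cough envelope
                 (click trains, long tone bursts, slow swells);
- ``music``    : a harmonic tone sequence with note changes;
- ``conversation``: 3-6 Hz amplitude-modulated band-limited noise with
                 formant-like resonances, two voice presets (low/high pitch);
- ``ambient``  : low-level 1/f noise.

Everything is deterministic per ``(label, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .frontend import TARGET_RATE, AudioClip, write_wav

LABELS = ("cough", "other", "music", "conversation", "ambient")
SPLITS = ("train", "val", "test")
SPLIT_FRACTIONS = {"train": 0.7, "val": 0.2, "test": 0.1}


class UnknownLabel(ValueError):
    pass


def _rng_for(label: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([LABELS.index(label), int(seed)]))


def _bandpass(x: np.ndarray, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="band", fs=TARGET_RATE,
                        output="sos")
    return signal.sosfilt(sos, x)


def _lowpass(x: np.ndarray, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, hi, btype="low", fs=TARGET_RATE, output="sos")
    return signal.sosfilt(sos, x)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Approximate 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / TARGET_RATE)
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=n)
    return pink / (np.abs(pink).max() + 1e-12)


def _normalize_peak(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.abs(x).max()
    return x * (peak / m) if m > 0 else x


def _cough(rng: np.random.Generator, n: int) -> np.ndarray:
    x = np.zeros(n)
    n_bursts = rng.integers(1, 3)
    for _ in range(n_bursts):
        dur = int(rng.uniform(0.08, 0.30) * TARGET_RATE)
        start = rng.integers(0, max(1, n - dur))
        t = np.arange(dur) / TARGET_RATE
        env = np.exp(-t / rng.uniform(0.02, 0.06))
        burst = _bandpass(rng.standard_normal(dur),
                          rng.uniform(250, 400), rng.uniform(2500, 3500))
        x[start:start + dur] += env * burst
    return _normalize_peak(x, rng.uniform(0.6, 0.95))


def _other(rng: np.random.Generator, n: int) -> np.ndarray:
    kind = rng.integers(0, 3)
    t_all = np.arange(n) / TARGET_RATE
    if kind == 0:  # click train: much shorter transients than a cough
        x = np.zeros(n)
        for _ in range(rng.integers(4, 9)):
            dur = int(rng.uniform(0.003, 0.012) * TARGET_RATE)
            start = rng.integers(0, n - dur)
            x[start:start + dur] += rng.standard_normal(dur)
    elif kind == 1:  # long steady tone burst (violates the decay envelope)
        f0 = rng.uniform(400, 2000)
        x = np.sin(2 * np.pi * f0 * t_all)
        dur = int(rng.uniform(0.6, 0.95) * n)
        start = rng.integers(0, n - dur)
        mask = np.zeros(n)
        mask[start:start + dur] = 1.0
        x *= mask
    else:  # slow noise swell, no sharp attack
        env = np.sin(np.pi * t_all / t_all[-1]) ** 2
        x = env * _bandpass(rng.standard_normal(n), 200, 4000)
    return _normalize_peak(x, rng.uniform(0.5, 0.9))


def _music(rng: np.random.Generator, n: int) -> np.ndarray:
    # Notes drawn from an equal-tempered scale, 3-5 harmonics each.
    x = np.zeros(n)
    note_len = int(rng.uniform(0.15, 0.35) * TARGET_RATE)
    pos = 0
    while pos < n:
        f0 = 220.0 * 2 ** (rng.integers(0, 25) / 12)
        dur = min(note_len, n - pos)
        t = np.arange(dur) / TARGET_RATE
        note = np.zeros(dur)
        for h in range(1, int(rng.integers(3, 6)) + 1):
            if f0 * h < TARGET_RATE / 2:
                note += np.sin(2 * np.pi * f0 * h * t) / h
        fade = min(dur // 10 + 1, 160)
        note[:fade] *= np.linspace(0, 1, fade)
        note[-fade:] *= np.linspace(1, 0, fade)
        x[pos:pos + dur] = note
        pos += dur
    return _normalize_peak(x, rng.uniform(0.6, 0.9))


#: Two formant presets emulating an even mix of lower- and higher-pitched
#: speakers: (F1, F2, F3) resonance centres in Hz.
_VOICE_PRESETS = ((500.0, 1500.0, 2500.0), (650.0, 1900.0, 2900.0))


def _conversation(rng: np.random.Generator, n: int) -> np.ndarray:
    formants = _VOICE_PRESETS[int(rng.integers(0, 2))]
    src = rng.standard_normal(n)
    x = np.zeros(n)
    for fc in formants:
        bw = rng.uniform(120, 220)
        x += _bandpass(src, max(50.0, fc - bw), fc + bw, order=2)
    t = np.arange(n) / TARGET_RATE
    syll = rng.uniform(3.0, 6.0)  # syllabic amplitude modulation
    env = 0.5 * (1 + np.sin(2 * np.pi * syll * t + rng.uniform(0, 2 * np.pi)))
    env = env ** 1.5 + 0.05
    return _normalize_peak(x * env, rng.uniform(0.5, 0.9))


def _ambient(rng: np.random.Generator, n: int) -> np.ndarray:
    x = _pink_noise(rng, n)
    hum = 0.2 * np.sin(2 * np.pi * 100.0 * np.arange(n) / TARGET_RATE)
    return _normalize_peak(_lowpass(x, 4000) + hum, rng.uniform(0.04, 0.10))


_GENERATORS = {
    "cough": _cough,
    "other": _other,
    "music": _music,
    "conversation": _conversation,
    "ambient": _ambient,
}


def synth_clip(label: str, seed: int, duration: float = 1.0) -> AudioClip:
    """One synthetic clip of *label*, deterministic per (label, seed)."""
    if label not in _GENERATORS:
        raise UnknownLabel(f"unknown class label {label!r}")
    if duration not in (1.0, 2.0):
        raise ValueError("duration must be 1.0 or 2.0 s")
    n = int(duration * TARGET_RATE)
    samples = _GENERATORS[label](_rng_for(label, seed), n)
    return AudioClip(samples=np.clip(samples, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Clip inventory with class labels and train/val/test assignment."""

    entries: pd.DataFrame  # columns: clip_id, label, split, seed, path

    def counts(self) -> pd.DataFrame:
        return self.entries.groupby(["label", "split"]).size().unstack(fill_value=0)

    def split(self, name: str) -> pd.DataFrame:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return self.entries[self.entries["split"] == name]

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(entries=pd.read_csv(path, keep_default_na=False))


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer apportionment of n by largest remainder."""
    exact = {k: n * f for k, f in fractions.items()}
    base = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(base.values())
    order = sorted(fractions, key=lambda k: exact[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def build_dataset(n_total: int,
                  labels: tuple[str, ...] = LABELS,
                  balanced: bool = True,
                  seed: int = 0,
                  duration: float = 1.0,
                  out_dir: str | Path | None = None) -> DatasetManifest:
    """Build a balanced, split dataset manifest (optionally writing WAVs).

    Clips are apportioned to classes (largest remainder when ``n_total`` is
    not a multiple of the class count), then within each class to
    train/val/test at 70/20/10 by a seeded shuffle.  Per-clip seeds are
    derived from the master seed, so any clip can be regenerated from its
    manifest row alone.  With ``out_dir`` set, clips are written as 16-bit
    16 kHz mono WAV files.
    """
    if n_total < len(labels):
        raise ValueError("n_total must be at least the number of classes")
    if balanced:
        per_class = _largest_remainder(
            n_total, {lab: 1.0 / len(labels) for lab in labels})
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
        draws = rng.multinomial(n_total, np.full(len(labels), 1 / len(labels)))
        per_class = dict(zip(labels, draws.tolist()))

    rows = []
    clip_index = 0
    for lab in labels:
        n_class = per_class[lab]
        split_counts = _largest_remainder(n_class, SPLIT_FRACTIONS)
        assignment = np.array(
            ["train"] * split_counts["train"] + ["val"] * split_counts["val"]
            + ["test"] * split_counts["test"], dtype=object)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), LABELS.index(lab)]))
        rng.shuffle(assignment)
        for j in range(n_class):
            clip_seed = int(np.random.SeedSequence(
                [int(seed), LABELS.index(lab), j]).generate_state(1)[0] % 2**31)
            rows.append({
                "clip_id": f"{lab}_{clip_index:05d}",
                "label": lab,
                "split": assignment[j],
                "seed": clip_seed,
                "path": "",
            })
            clip_index += 1

    entries = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for row in entries.itertuples():
            p = out_dir / f"{row.clip_id}.wav"
            write_wav(p, synth_clip(row.label, row.seed, duration))
            paths.append(str(p))
        entries["path"] = paths
    return DatasetManifest(entries=entries)


def load_clip(row, duration: float = 1.0) -> AudioClip:
    """Materialize a manifest row: from its WAV if written, else re-synthesize."""
    from .frontend import read_wav

    path = getattr(row, "path", "")
    if isinstance(path, str) and path:
        return read_wav(path, target_duration=duration)
    return synth_clip(row.label, int(row.seed), duration)


# ---------------------------------------------------------------------------
# Analytic baseline features
# ---------------------------------------------------------------------------

_BANDS = ((0, 300), (300, 1000), (1000, 3000), (3000, 8000))


def clip_features(clip: AudioClip) -> np.ndarray:
    """Hand-crafted features: band-energy fractions, envelope kurtosis, level.

    Used by the nearest-centroid baseline that lower-bounds what any trained
    classifier should achieve on this corpus, and in sanity checks that the
    synthetic classes are distinguishable at all.
    """
    x = clip.samples
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / TARGET_RATE)
    total = spec.sum() + 1e-12
    fracs = [spec[(freqs >= lo) & (freqs < hi)].sum() / total
             for lo, hi in _BANDS]
    env = np.abs(signal.hilbert(x))
    mu, sd = env.mean(), env.std() + 1e-12
    kurt = float(np.mean(((env - mu) / sd) ** 4))
    rms = float(np.sqrt(np.mean(x ** 2)))
    return np.array(fracs + [np.log10(kurt + 1e-6), np.log10(rms + 1e-6)])


def band_energy_ratio(clip: AudioClip, lo: float = 300, hi: float = 3000) -> float:
    """Fraction of spectral energy inside [lo, hi) Hz."""
    x = clip.samples
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / TARGET_RATE)
    total = spec.sum() + 1e-12
    return float(spec[(freqs >= lo) & (freqs < hi)].sum() / total)
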