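"""From waveform to classifier input: gate, spectrogram, resize, standardize.

Shows the fixed shapes of the preprocessing chain on a synthetic cough and
why the silence gate must run on the raw amplitude, before normalization.
"""

import numpy as np

from thermocough.audio import frontend, synth

cough = synth.synth_clip("cough", seed=7)
print(f"clip: {len(cough.samples)} samples at {cough.rate} Hz "
      f"(peak {np.abs(cough.samples).max():.2f})")

spec = frontend.compute_spectrogram(cough)
x = frontend.prepare_model_input(spec)
print(f"spectrogram {spec.magnitudes.shape} (62.5 Hz bins, 6.25 ms hop) "
      f"-> model input {x.shape}, mean {x.mean():.1e}, std {x.std():.3f}")

quiet = frontend.AudioClip(samples=0.002 * np.sin(
    2 * np.pi * 500 * np.arange(16000) / 16000))
print(f"quiet 0.002-amplitude tone: gate says silence = "
      f"{frontend.silence_gate(quiet)}")
normalized = frontend.peak_normalize(quiet)
print(f"after peak normalization its RMS becomes "
      f"{np.sqrt((normalized.samples**2).mean()):.2f} — a gate placed after "
      "normalization would wrongly classify it, which is why the gate runs "
      "first.")
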