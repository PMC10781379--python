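# Methods

This note documents the models, parameter choices and numerical decisions
behind `thermocough`, and what the synthetic test conditions do and do not
demonstrate about real hardware.

## Thermal measurement model

**Sensor.** The imager is a 24x32 thermopile array (110° x 75° field of
view, modelled only as a pixel grid — optics, emissivity and distance
effects are out of scope).  Its error is modelled as an affine map plus
noise: `raw = gain * true + offset + N(0, noise_sd)` per pixel.  This is the
error class the two-point calibration cancels exactly; real thermopiles also
have non-linear and per-pixel components, so simulated exactness is an upper
bound on hardware behaviour, not a prediction of it.

**References.** Two Peltier patches are regulated at 33 °C and 38 °C — just
below and at the clinical decision range — so the calibration line is
anchored where accuracy matters.  Each Peltier is a first-order plant

    dT/dt = -k_loss (T - T_amb) + k_heat * d,   d ∈ [0, 1],

with defaults `k_heat = 0.5 °C/s` (full-duty heating rate),
`k_loss = 0.02 s⁻¹` (passive loss), `T_amb = 22 °C`.  No Peltier thermal
constants were available for the reference hardware; these are stand-ins
chosen to give a realistic warm-up of roughly two minutes.  Integration uses
the exact exponential step for piecewise-constant duty rather than forward
Euler, so open-loop trajectories match the closed form
`T(t) = T_inf + (T_0 - T_inf) e^(-k_loss t)` to floating-point precision —
this is what makes the simulator usable as its own oracle in tests.

**PID.** Discrete PID (`dt = 0.5 s`) drives the PWM duty cycle.  Defaults
`kp = 2, ki = 0.5, kd = 1`, integral clamp ±10 plus conditional
integration (the integral is frozen while the output is saturated and the
error would push it further).  Two values were genuinely open: much larger
proportional gains (e.g. kp = 8) make the proportional term span the whole
duty range for a 0.125 °C error and leave a bang-bang limit cycle of about
±0.1 °C, and a bare integral clamp without conditional integration winds up
during the saturated warm-up ramp and overshoots by several degrees.  The
chosen defaults settle both setpoints to machine precision after ~300 s
while still completing warm-up in about two simulated minutes.

**Self-detection of the references.** During warm-up nothing else in the
scene may change temperature; the references are then the only pixels with a
large rise score `mean(last 5 frames) - mean(first 5 frames)`.  Pixels above
half the low setpoint's rise (ambient estimated as the first frame's median)
are grouped into 4-connected components; the two largest are the references,
the hotter one (final-window mean) being the 38 °C anchor.  Both regions
dilated by a 1-pixel margin form the exclusion mask, so bleed-over pixels at
patch borders cannot win the patient argmax.  Fewer than two components is a
detection failure; components that touch (even diagonally) are ambiguous and
rejected rather than guessed at.

**Calibration and measurement.** Each measurement frame is recalibrated:
the anchor raw values are the current frame's mean over each detected
region, and the line

    corrected = slope * raw + intercept,
    slope = (T_high - T_low) / (raw_high - raw_low)

is exact at both anchors by construction.  The patient is the hottest
non-excluded pixel; its 3x3 neighbourhood mean (window intersected with the
grid at borders, ties broken by smallest row-major index) is pushed through
the line.  For the *campaign and monitor*, the patient pixel is located on
the 3x3-mean smoothed frame: for interior-hot scenes this coincides with
the plain argmax, and for a flat-topped object (the uniform validation
plate) it guarantees the averaging window lies inside the object instead of
straddling its corner — without this, a noise-free measurement of a uniform
plate would be biased by ambient pixels in the window.

**Reference thermometers** are modelled as plant truth plus a configurable
bias bounded at ±1 °C, the stated accuracy class of the contact sensor used
on the reference design.  Default bias is zero.

**Validation rig.** An 11 x 11 cm temperature-controlled plate stands in
for a patient's head; it maps to a 9x9-pixel block divided 3x3 into nine
zones with per-zone offsets (|offset| ≤ 0.5 °C) modelling surface
non-uniformity.  The campaign protocol per plate temperature: warm up from
ambient (120 s), self-detect, calibrate, present the plate, measure, record
`(measured, validation, |error|)` — emitted as CSV with header
`measured_C,validation_C,error_C`.

**Bundled bench table.** The package ships a 25-row reference table of
bench measurements (measured vs plate-thermometer temperature).  Its error
column is internally consistent (`|measured - validation|` to print
rounding, max 0.9 °C, min 0.023 °C).  The separately quoted headline
average of 0.28 °C for this bench campaign is *not* recoverable from the
printed rows — their plain mean is ≈ 0.378 °C, and restricting to the
36.5-38.5 °C range does not close the gap — so the package verifies the
table row-wise and by its extremes and treats the headline average as
unexplained.

## Audio pipeline

**Clip format.** Mono, 16 kHz, 16-bit, 1 s (16 000 samples) or 2 s (32 000
samples).  Arbitrary input is mixed down by channel mean, polyphase
resampled, and right-trimmed or zero-padded.

**Silence gate before normalization.** The gate skips inference when the
*raw* RMS is below 1 % of full scale (strict inequality at the threshold).
Ordering is load-bearing: peak normalization rescales arbitrarily quiet
clips to full level, so a gate placed after it never fires.  The pipeline
therefore gates first and normalizes second, and a regression test pins
this.

**Spectrogram.** 256-point FFT, 256-sample Hann window, hop 100 samples,
end-padding so the frame count is `ceil(N/hop)`.  This yields 129 frequency
bins (62.5 Hz spacing) x 160 frames for 1 s, the one simple parameterization
consistent with the target input geometry; a "30 ms window" (480 samples)
would give 241 bins and is treated as a UI-level description rather than an
STFT parameter.  For 2 s clips the same front end yields 129 x 320; a
reported 2 s input size of 129 x 246 matches no standard parameterization of
the stated settings and is flagged rather than imitated — the package keeps
one consistent front end.

**Model input.** The classifier's two leading stages are data
transformations, kept in the front end: bilinear resampling of the time axis
from 160 to 124 columns (half-pixel convention, corner alignment off), then
per-sample standardization `(x - mean) / max(std, 1e-6)`.  Statistics are
per sample, not corpus-level; a constant spectrogram maps to all zeros via
the epsilon rule.

## Synthetic audio corpus

Five classes — cough, other, music, conversation, ambient — with seeded,
fully deterministic generators (`(label, seed)` fixes the waveform).  Cough:
1-2 exponentially decaying broadband bursts, 80-300 ms, band-emphasized
300-3500 Hz.  Other: transients and tones violating the cough envelope
(click trains, long tone bursts, slow swells) — deliberately including
cough-adjacent and music-adjacent material so the classification problem is
not trivially separable.  Music: equal-tempered harmonic note sequences.
Conversation: formant-filtered noise amplitude-modulated at 3-6 Hz, with two
voice presets emulating an even low/high-pitch speaker mix.  Ambient:
low-level 1/f noise plus mains hum, quiet (RMS ≈ 0.03-0.07) but above the
silence gate.

The generator emulates the *statistical separability* of the real corpora,
not their acoustics: no recording channels, room reverberation, overlapping
sources, or real cough variability (dry coughs, "S" phonemes, short coughs
were the documented hard cases on real data).  Accuracies measured here
therefore validate the pipeline's mechanics — shapes, training loop,
bookkeeping, streaming logic — and do not transfer to real microphones.

Datasets are balanced per class (largest-remainder apportionment when the
total is not divisible), split 70/20/10 into train/validation/test by a
seeded per-class shuffle, again with largest-remainder rounding; manifests
are CSV (`clip_id,label,split,seed,path`) and every clip is regenerable
from its manifest row.

## Classifier

A compact CNN over the 129 x 124 input, implemented directly in numpy
(im2col convolutions; no deep-learning framework dependency): two
convolution stages (16 then 32 filters, 3x3, each downsampling by 2 via
stride), a 64-unit dense stage with dropout 0.25, softmax over K ∈ {2, 5}
classes (default 5).  He initialization and dropout are seeded; training is
Adam (lr 1e-3), batch 32, a fixed 12 epochs with per-epoch validation
feedback.  These hyperparameters were open choices fixed in
`ModelConfig`/`TrainConfig` for reproducibility.  Parameters are float32;
batch and per-item forward passes agree to ~1e-5, which is the tolerance the
batch-invariance test uses.

The analytic reference is a nearest-centroid classifier over band-energy
fractions (0-0.3, 0.3-1, 1-3, 3-8 kHz), envelope kurtosis and log-RMS.  It
scores ≥ 0.8 on held-out synthetic data — evidence the corpus is separable,
so the CNN's accuracy target is meaningful — and the trained CNN must beat
it on the same split.

**Streaming.** 1 s windows slide by 0.5 s (50 % overlap) so a cough cannot
vanish by straddling a window boundary — the documented failure mode of
non-overlapping streaming windows.  Silence-gated windows are skipped;
consecutive cough windows separated by ≤ 0.5 s merge into one event whose
confidence is the maximum window cough probability.

## Telemetry

Packets are flat JSON with fixed key order `id, time, type,
temperature|audio`, all-lowercase keys (one convention chosen where the
reference description mixes cases).  `id` is the device's common name plus
the last four hex digits of its MAC, uppercase.  `time` is integer epoch
seconds.  Thermal packets are emitted only strictly above 38.0 °C; cough
packets carry the clip's complete WAV bytes base64-encoded (42 728
characters for 1 s).  Discovery: the server broadcasts
`{"service", "ip", "port"}` JSON datagrams on UDP (default port 5005);
the first valid announcement wins and later ones refresh the endpoint.
Delivery: newline-delimited UTF-8 JSON over TCP with a `{"ack": id}` reply
— the framing and ack are this package's conventions, chosen as the
simplest interoperable ones.  No TLS or authentication (out of scope).

WAV round-tripping uses a 32768 scale factor on both write and read so that
write→read→write is the identity on PCM words (exact full-scale +1.0 clips
to 32767).

## Monitor loop

One warm-up calibration (failure aborts with a diagnostic), then per-frame
measurement with per-frame recalibration and sliding-window audio
classification; the two paths are processed independently and their events
are serialized through a single time-ordered queue, making runs bit
reproducible under fixed seeds and scripted sources.  Fever packets are
debounced per episode: one packet at the first strictly-above-38 °C frame,
re-armed only after the reading drops 0.2 °C below threshold, so a feverish
patient does not generate a packet per frame.

## Problem sizes in the test suite

Unit tests run on 60 clips per class with 6 training epochs; the end-to-end
classifier check runs at 500 clips per class (350/100/50 per class after the
split) with the default 12 epochs, where the CNN reaches ≥ 0.90 held-out
accuracy and beats the analytic baseline.  Thermal checks use 120 s
warm-ups at 1 frame/s and 300-600 s plant simulations at dt = 0.5 s.  These
sizes are the package's chosen desk-scale study conditions; larger corpora
change runtimes, not code paths.

## Known limitations

- Radiometric physics (emissivity, distance, field-of-view aberrations) is
  not modelled; the affine sensor is an idealization.
- The face and plate are hard-edged objects with no point-spread blur —
  deliberate, so that argmax-based oracles in the tests stay exact.
- Synthetic audio realism is a non-goal; reported accuracies characterize
  the pipeline, not clinical performance.
- The whole system is simulation-first: hardware drivers, I2C/I2S buses and
  deployment concerns are explicitly out of scope.
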