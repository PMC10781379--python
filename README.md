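# thermocough

Non-contact fever and cough monitoring as a fully simulated, tested software
pipeline.  The package is for engineers and researchers working on
point-of-care screening devices who need the *algorithms* of such a device —
self-calibrating thermopile temperature measurement, spectrogram-based cough
classification, and event telemetry — runnable, testable and reproducible
without any hardware.

Three things live here:

1. **Thermal path** — a seeded simulator of a 24x32 thermopile viewing two
   PID-regulated Peltier reference patches (33 °C and 38 °C), and the
   measurement method built on it: self-detect the references from warm-up
   temperature rise, fit a per-frame two-point calibration, locate the
   patient as the hottest non-reference pixel, average its 3x3
   neighbourhood, and correct it.  The calibration line

   `corrected = slope · raw + intercept`, with
   `slope = (T_high − T_low) / (raw_high − raw_low)`,

   is exact at both anchors, so any affine sensor error (gain/offset) is
   cancelled identically.  A nine-zone validation-plate rig reproduces the
   bench protocol behind the bundled 25-row reference table.

2. **Audio path** — a deterministic front end (mono 16 kHz clips → silence
   gate on *raw* amplitude → peak normalization → 129x160 magnitude
   spectrogram → 129x124 standardized model input), a seeded five-class
   synthetic audio generator (cough / other / music / conversation /
   ambient) with 70/20/10 dataset manifests, a compact numpy CNN classifier
   (conv 16 → conv 32 → dense 64 → softmax), and streaming detection with
   1 s windows, 50 % overlap and event debouncing.

3. **Telemetry** — JSON event packets (`id, time, type,
   temperature|audio`), device ids from the MAC's last four hex digits, the
   strict above-38 °C fever rule, base64 WAV payloads, UDP server discovery,
   newline-delimited JSON over TCP, and a loopback mock server.

## Worked example

Calibrated measurement through a deliberately mis-calibrated sensor
(`examples/01_thermal_calibration.py`):

```
warm-up: 120 frames; raw high-reference reading 37.14 C (truth 38.00 C)
calibration line: corrected = 1.0753 * raw + -1.935
patient pixel (15, 15): raw 3x3 mean 36.58 C, corrected 37.4000 C
```

The sensor (gain 0.93, offset +1.8 °C) misreads the 38 °C reference by
almost a degree, but the two-point line fitted from the references recovers
the true 37.40 °C face temperature exactly — the affine error cancels by
construction.

Training the classifier on synthetic audio
(`examples/04_train_classifier.py`, 100 clips per class):

```
epoch losses: [3.082, 0.467, 0.15, 0.083, 0.037, 0.039, 0.029, 0.023]
held-out (test split) accuracy: 0.980
band-energy nearest-centroid baseline: 0.920
```

The CNN beats the analytic band-energy baseline on the same held-out split;
at the 500-clips-per-class scale used in the test suite it reaches 1.00
held-out accuracy against a 0.936 baseline.  These numbers characterize the
pipeline on the synthetic corpus, not clinical performance (see
`docs/methods.md`).

The other examples cover the validation campaign, the audio front end,
streaming detection with debouncing, the telemetry loopback, and a full
monitor session; each prints what it computes and says what the numbers
mean.

A thin CLI wraps the same functions:

```
thermocough calibrate --noise-sd 0.1
thermocough validate --out campaign.csv
thermocough build-dataset --n-total 5000 --manifest manifest.csv
thermocough train --manifest manifest.csv --model-out model.npz
thermocough serve-mock          # loopback server
thermocough monitor --model model.npz --udp-port 5005
```

## Grid and file conventions

Thermal frames are `(24, 32)` arrays of °C, row-major, 0-based, row 0 at
the top; sequences serialize to long-form CSV
(`frame_index,row,col,value`) or `.npz`.  Audio is 16-bit PCM mono 16 kHz
WAV.  Dataset manifests are CSV (`clip_id,label,split,seed,path`); every
clip is regenerable from its `(label, seed)` pair.  The packet wire format
is documented by `src/thermocough/schemas/event_packet.schema.json`.

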