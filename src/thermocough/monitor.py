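"""Integrated monitor: calibrated fever screening + streaming cough detection.

`run_monitor` wires the pieces together the way the deployed device does:
one warm-up calibration pass, then per-frame temperature measurement with
per-frame recalibration, concurrent sliding-window cough classification on
the audio stream, and JSON telemetry for every detection.  Thermal and audio
paths are processed independently and their events are serialized through a
single time-ordered queue, so a fixed seed plus scripted sources reproduces
the event log exactly.

Fever packets are debounced per above-threshold *episode*: one packet when
the corrected temperature first exceeds the threshold, re-armed only after
it drops ``rearm_delta`` below the threshold again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from .audio.classifier import StreamEvent, classify_stream
from .audio.frontend import TARGET_RATE, AudioClip
from .telemetry.packets import (
    EventPacket,
    build_cough_event,
    build_thermal_event,
    make_device_id,
)
from .telemetry.transport import ServerEndpoint, TransportError, send_event
from .thermal.calib import (
    PeltierRegions,
    ReferencesNotFound,
    calibrate_frame,
    detect_peltier_regions,
    measure_patient,
)
from .thermal.sim import (
    Face,
    SensorModel,
    ThermalFrame,
    default_scene,
    render_frame,
    simulate_warmup,
)

log = logging.getLogger(__name__)


@dataclass
class MonitorConfig:
    """All monitor knobs with deployment defaults."""

    fever_threshold: float = 38.0   # strict > rule, deg C
    rearm_delta: float = 0.2        # re-arm after dropping this far below
    ref_low: float = 33.0           # reference thermometer readings, deg C
    ref_high: float = 38.0
    frame_period: float = 1.0       # s
    audio_window: float = 1.0       # s
    audio_hop: float = 0.5          # s
    silence_threshold: float = 0.01
    device_name: str = "E"
    device_mac: str = "00:11:22:33:12:34"
    epoch_base: int = 0             # epoch seconds of simulated t = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.fever_threshold <= 42.0):
            raise ValueError("fever threshold outside sensor range")
        if self.ref_low >= self.ref_high:
            raise ValueError("calibration setpoints must be distinct, low < high")

    @classmethod
    def from_yaml(cls, path) -> "MonitorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class MonitorResult:
    """Everything a monitor run produced, in emission order."""

    event_log: list[dict] = field(default_factory=list)
    packets: list[EventPacket] = field(default_factory=list)
    delivered: int = 0
    regions: PeltierRegions | None = None


def run_monitor(cfg: MonitorConfig,
                warmup_frames: Sequence[ThermalFrame],
                frames: Sequence[ThermalFrame],
                audio_stream: np.ndarray,
                model,
                sink: ServerEndpoint | Callable[[EventPacket], None] | None = None,
                ) -> MonitorResult:
    """Run the full monitor over scripted or simulated sources.

    ``sink`` may be a TCP endpoint, any callable, or None (offline mode:
    events are logged locally only).  Every emitted packet corresponds to a
    logged detection and vice versa.
    """
    identity = make_device_id(cfg.device_name, cfg.device_mac)
    result = MonitorResult()

    try:
        regions = detect_peltier_regions(list(warmup_frames),
                                         ref_low=cfg.ref_low,
                                         ref_high=cfg.ref_high)
    except ReferencesNotFound as exc:
        log.error("calibration failed: %s", exc)
        raise
    result.regions = regions

    # --- thermal path: per-frame recalibrated measurement, debounced ---
    pending: list[tuple[float, dict, EventPacket | None]] = []
    armed = True
    for frame in frames:
        curve = calibrate_frame(frame, regions)
        reading = measure_patient(frame, regions, curve)
        entry = {"time": frame.timestamp, "kind": "temperature",
                 "corrected_C": reading.corrected, "pixel": reading.pixel}
        packet = None
        if armed and reading.corrected > cfg.fever_threshold:
            packet = build_thermal_event(
                identity, reading.corrected,
                time_s=cfg.epoch_base + int(frame.timestamp),
                threshold=cfg.fever_threshold)
            armed = False
            entry["kind"] = "fever"
        elif not armed and (reading.corrected
                            < cfg.fever_threshold - cfg.rearm_delta):
            armed = True
        pending.append((frame.timestamp, entry, packet))

    # --- audio path: sliding-window classification with merging ---
    if len(audio_stream) >= int(cfg.audio_window * TARGET_RATE):
        events: list[StreamEvent] = classify_stream(
            audio_stream, model, window=cfg.audio_window, hop=cfg.audio_hop,
            gate_threshold=cfg.silence_threshold)
    else:
        log.warning("audio underrun: stream shorter than one window, skipped")
        events = []
    n_clip = int(cfg.audio_window * TARGET_RATE)
    for ev in events:
        start_idx = int(ev.start * TARGET_RATE)
        samples = audio_stream[start_idx:start_idx + n_clip]
        if len(samples) < n_clip:
            samples = np.pad(samples, (0, n_clip - len(samples)))
        clip = AudioClip(samples=np.asarray(samples, dtype=np.float64))
        packet = build_cough_event(identity, clip,
                                   time_s=cfg.epoch_base + int(ev.start))
        entry = {"time": ev.start, "kind": "cough", "end": ev.end,
                 "confidence": ev.confidence}
        pending.append((ev.start, entry, packet))

    # --- single ordered emission queue ---
    pending.sort(key=lambda item: item[0])
    for _t, entry, packet in pending:
        if packet is not None:
            entry["packet"] = packet.to_dict()
            result.packets.append(packet)
            if sink is None:
                log.info("offline: logged %s event locally", packet.type)
            elif isinstance(sink, ServerEndpoint):
                try:
                    send_event(sink, packet)
                    result.delivered += 1
                except TransportError as exc:
                    log.error("delivery failed: %s", exc)
                    entry["delivery_error"] = str(exc)
            else:
                sink(packet)
                result.delivered += 1
        result.event_log.append(entry)
    return result


# ---------------------------------------------------------------------------
# Scripted sources for tests, examples and the CLI
# ---------------------------------------------------------------------------

def scripted_thermal_source(face_temps: Sequence[float],
                            sensor: SensorModel,
                            warmup_duration: float = 120.0,
                            frame_period: float = 1.0,
                            face_center: tuple[float, float] = (16.0, 16.0),
                            face_radius: float = 3.0,
                            ) -> tuple[list[ThermalFrame], list[ThermalFrame]]:
    """Warm-up frames plus one measurement frame per scripted face temperature.

    The warm-up scene contains only the reference patches (nothing else may
    change temperature during self-detection); the face then appears with
    the scripted temperature trajectory while the references hold their
    setpoints.
    """
    scene = default_scene()
    warmup = simulate_warmup(scene, sensor, warmup_duration, frame_period)
    frames = []
    for k, temp in enumerate(face_temps):
        scene.face = Face(center=face_center, radius=face_radius, temp=temp)
        t = warmup_duration + (k + 1) * frame_period
        frames.append(render_frame(scene, sensor, t,
                                   frame_index=len(warmup) + k))
    scene.face = None
    return warmup, frames


def cough_in_ambient_stream(duration: float, cough_times: Sequence[float],
                            seed: int = 0,
                            ambient_level: float = 0.05) -> np.ndarray:
    """An ambient-noise stream with synthetic cough bursts at given times."""
    from .audio.synth import synth_clip

    n = int(duration * TARGET_RATE)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    stream = ambient_level * rng.standard_normal(n)
    stream = np.convolve(stream, np.ones(8) / 8, mode="same")  # soften
    for i, t0 in enumerate(cough_times):
        burst = synth_clip("cough", seed=1000 + seed * 100 + i).samples
        start = int(t0 * TARGET_RATE)
        end = min(n, start + len(burst))
        stream[start:end] += burst[:end - start]
    return np.clip(stream, -1.0, 1.0)
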