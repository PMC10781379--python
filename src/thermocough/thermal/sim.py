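"""Synthetic thermopile scene simulator.

Emulates what a low-cost 24x32 far-infrared thermopile array sees while a
self-calibrating fever screener warms up: two Peltier reference patches under
PID control, an optional face blob, an ambient background, and a simple
affine-plus-noise sensor error model.  A nine-zone aluminium validation plate
(the bench stand-in for a patient's head) is modelled as well, so the whole
calibration and measurement chain can be exercised without hardware.

Conventions
-----------
Frames are ``(24, 32)`` numpy arrays of degrees Celsius, row-major, 0-based,
row 0 at the top.  All randomness flows through a single integer seed on
:class:`SensorModel`; identical seeds give bit-identical frame sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

GRID_ROWS = 24
GRID_COLS = 32
#: Field of view of the emulated imager in degrees (horizontal, vertical).
#: Informational only: optics are not modelled.
FOV_DEG = (110.0, 75.0)

#: Reference setpoints bracketing the clinical range of interest (deg C).
SETPOINT_LOW = 33.0
SETPOINT_HIGH = 38.0


class ConfigurationError(ValueError):
    """Raised when a scene, rig or controller is configured inconsistently."""


# ---------------------------------------------------------------------------
# Plant and controller
# ---------------------------------------------------------------------------

@dataclass
class PeltierPlant:
    """First-order thermal model of a Peltier reference patch.

    The patch obeys ``dT/dt = -k_loss * (T - ambient) + k_heat * duty`` with
    duty in [0, 1].  At constant duty the steady state is
    ``ambient + k_heat * duty / k_loss``; integration uses the exact
    exponential step for a piecewise-constant duty, so an open-loop run
    reproduces the analytic approach to steady state to floating-point
    precision.
    """

    temp: float = 22.0
    setpoint: float = SETPOINT_HIGH
    k_heat: float = 0.5   # deg C per second at full duty
    k_loss: float = 0.02  # 1/s passive loss toward ambient
    ambient: float = 22.0

    def __post_init__(self) -> None:
        if not (self.k_heat > 0 and self.k_loss > 0):
            raise ConfigurationError("k_heat and k_loss must be positive")

    def steady_state(self, duty: float) -> float:
        """Analytic temperature reached if *duty* were held forever."""
        return self.ambient + self.k_heat * duty / self.k_loss

    def step(self, duty: float, dt: float) -> "PeltierPlant":
        """Advance one interval of length *dt* seconds at constant *duty*."""
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        target = self.steady_state(duty)
        new_temp = target + (self.temp - target) * math.exp(-self.k_loss * dt)
        return replace(self, temp=new_temp)


@dataclass
class PIDState:
    """Discrete PID controller state driving a Peltier duty cycle.

    Gains default to values that bring the plant from room temperature to its
    setpoint in roughly two simulated minutes.  The duty is clamped to [0, 1]
    and the integral term is clamped to ``+-integral_clamp``; additionally the
    integral is frozen while the output is saturated and the error would push
    it further into saturation (conditional anti-windup), which prevents the
    large overshoot a bare clamp would allow during the warm-up ramp.
    """

    kp: float = 2.0
    ki: float = 0.5
    kd: float = 1.0
    dt: float = 0.5
    integral: float = 0.0
    prev_error: float = 0.0
    integral_clamp: float = 10.0
    duty: float = 0.0

    def __post_init__(self) -> None:
        for g in (self.kp, self.ki, self.kd, self.dt):
            if not math.isfinite(g):
                raise ConfigurationError("PID gains and dt must be finite")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")


def step_pid(plant: PeltierPlant, pid: PIDState, setpoint: float
             ) -> tuple[float, PeltierPlant, PIDState]:
    """One closed-loop control step: compute duty, then advance the plant.

    Returns ``(duty, plant', pid')`` without mutating the inputs.
    """
    error = setpoint - plant.temp
    derivative = (error - pid.prev_error) / pid.dt
    candidate_integral = pid.integral + error * pid.dt
    candidate_integral = float(np.clip(candidate_integral,
                                       -pid.integral_clamp, pid.integral_clamp))
    raw = pid.kp * error + pid.ki * candidate_integral + pid.kd * derivative
    duty = float(np.clip(raw, 0.0, 1.0))
    # Conditional anti-windup: only accept the new integral when the output
    # is unsaturated or the error drives it out of saturation.
    saturated_high = raw > 1.0 and error > 0
    saturated_low = raw < 0.0 and error < 0
    integral = pid.integral if (saturated_high or saturated_low) else candidate_integral
    new_pid = replace(pid, integral=integral, prev_error=error, duty=duty)
    new_plant = plant.step(duty, pid.dt)
    return duty, new_plant, new_pid


def simulate_plant(setpoint: float, duration: float, *,
                   plant: PeltierPlant | None = None,
                   pid: PIDState | None = None) -> pd.DataFrame:
    """Closed-loop warm-up of a single Peltier from ambient.

    Returns a DataFrame with columns ``time_s, temp_C, duty`` sampled at the
    controller period, starting at t = dt (state after the first step).
    """
    plant = plant if plant is not None else PeltierPlant(setpoint=setpoint)
    pid = pid if pid is not None else PIDState()
    n_steps = int(round(duration / pid.dt))
    rows = []
    for i in range(n_steps):
        duty, plant, pid = step_pid(plant, pid, setpoint)
        rows.append(((i + 1) * pid.dt, plant.temp, duty))
    return pd.DataFrame(rows, columns=["time_s", "temp_C", "duty"])


# ---------------------------------------------------------------------------
# Scene and sensor
# ---------------------------------------------------------------------------

@dataclass
class PeltierPatch:
    """A rectangular reference patch in the imager's field of view."""

    origin: tuple[int, int]       # (row, col) of top-left pixel
    height: int
    width: int
    plant: PeltierPlant = field(default_factory=PeltierPlant)

    @property
    def rows(self) -> slice:
        return slice(self.origin[0], self.origin[0] + self.height)

    @property
    def cols(self) -> slice:
        return slice(self.origin[1], self.origin[1] + self.width)

    def mask(self) -> np.ndarray:
        m = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class Face:
    """A hard-edged warm disc standing in for a patient's face."""

    center: tuple[float, float]   # (row, col), fractional allowed
    radius: float                 # pixels
    temp: float                   # deg C

    def mask(self) -> np.ndarray:
        rr, cc = np.mgrid[0:GRID_ROWS, 0:GRID_COLS]
        return ((rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
                <= self.radius ** 2)


@dataclass
class ThermalScene:
    """Static layout of what the thermopile views."""

    ambient_temp: float = 22.0
    face: Face | None = None
    peltier_patches: list[PeltierPatch] = field(default_factory=list)
    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    fov_deg: tuple[float, float] = FOV_DEG

    def __post_init__(self) -> None:
        if (self.grid_rows, self.grid_cols) != (GRID_ROWS, GRID_COLS):
            raise ConfigurationError(
                f"grid must be {GRID_ROWS}x{GRID_COLS}")
        for p in self.peltier_patches:
            r0, c0 = p.origin
            if not (0 <= r0 and r0 + p.height <= GRID_ROWS
                    and 0 <= c0 and c0 + p.width <= GRID_COLS):
                raise ConfigurationError(f"patch {p.origin} outside grid")
        if len(self.peltier_patches) >= 2:
            masks = [p.mask() for p in self.peltier_patches]
            for i in range(len(masks)):
                for j in range(i + 1, len(masks)):
                    if (masks[i] & masks[j]).any():
                        raise ConfigurationError("Peltier patches overlap")
        if self.face is not None and not (30.0 <= self.face.temp <= 42.0):
            raise ConfigurationError("face temperature must lie in [30, 42] C")

    def true_field(self) -> np.ndarray:
        """Ground-truth temperature of every pixel, before the sensor."""
        field_ = np.full((GRID_ROWS, GRID_COLS), self.ambient_temp, dtype=float)
        if self.face is not None:
            field_[self.face.mask()] = self.face.temp
        for p in self.peltier_patches:
            field_[p.rows, p.cols] = p.plant.temp
        return field_


@dataclass
class SensorModel:
    """Affine gain/offset error plus i.i.d. Gaussian pixel noise.

    This is the error the two-point calibration is designed to cancel.  Noise
    is generated from an internal stream seeded once at construction; frame
    ``k`` of a run always receives the ``k``-th noise draw, so a fixed seed
    reproduces a sequence bit for bit.
    """

    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    def observe(self, true_field: np.ndarray, frame_index: int = 0) -> np.ndarray:
        raw = self.gain * true_field + self.offset
        if self.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed), int(frame_index)]))
            raw = raw + rng.normal(0.0, self.noise_sd, size=raw.shape)
        return raw


@dataclass
class ThermalFrame:
    """One raw thermopile frame: 24x32 readings in deg C plus a timestamp."""

    values: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_ROWS, GRID_COLS):
            raise ConfigurationError(
                f"frame shape must be {(GRID_ROWS, GRID_COLS)}")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("frame contains non-finite values")


def render_frame(scene: ThermalScene, sensor: SensorModel, timestamp: float,
                 frame_index: int = 0) -> ThermalFrame:
    """Render one raw frame of *scene* through *sensor*.

    ``frame_index`` selects the noise draw so that re-rendering frame ``k``
    with the same seed reproduces it exactly.
    """
    raw = sensor.observe(scene.true_field(), frame_index)
    return ThermalFrame(values=raw, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Warm-up simulation
# ---------------------------------------------------------------------------

def default_scene(ambient: float = 22.0, face: Face | None = None,
                  setpoints: tuple[float, float] = (SETPOINT_LOW, SETPOINT_HIGH),
                  ) -> ThermalScene:
    """Two 4x4 reference patches near the top of the frame.

    The low reference sits at (4, 4), the high at (4, 24); both start at
    ambient.  This mirrors references mounted at the image periphery, away
    from where a patient appears.
    """
    low = PeltierPatch(origin=(4, 4), height=4, width=4,
                       plant=PeltierPlant(temp=ambient, setpoint=setpoints[0],
                                          ambient=ambient))
    high = PeltierPatch(origin=(4, 24), height=4, width=4,
                        plant=PeltierPlant(temp=ambient, setpoint=setpoints[1],
                                           ambient=ambient))
    return ThermalScene(ambient_temp=ambient, face=face,
                        peltier_patches=[low, high])


def simulate_warmup(scene: ThermalScene, sensor: SensorModel, duration: float,
                    frame_period: float = 1.0,
                    pid: PIDState | None = None) -> list[ThermalFrame]:
    """Run both reference patches under PID toward their setpoints.

    The scene is otherwise static (no moving warm objects), matching the
    constraint under which reference self-detection by temperature
    fluctuation is valid.  Frames are emitted every ``frame_period`` seconds,
    the controller runs at its own (finer) period in between.
    """
    if not scene.peltier_patches:
        raise ConfigurationError("warm-up needs at least one Peltier patch")
    if duration < frame_period:
        raise ConfigurationError("duration must cover at least one frame")
    pid_template = pid if pid is not None else PIDState()
    pids = [replace(pid_template) for _ in scene.peltier_patches]
    plants = [p.plant for p in scene.peltier_patches]

    n_frames = int(duration // frame_period)
    steps_per_frame = max(1, int(round(frame_period / pid_template.dt)))
    frames: list[ThermalFrame] = []
    for k in range(n_frames):
        for _ in range(steps_per_frame):
            for i, patch in enumerate(scene.peltier_patches):
                _, plants[i], pids[i] = step_pid(plants[i], pids[i],
                                                 patch.plant.setpoint)
        for patch, plant in zip(scene.peltier_patches, plants):
            patch.plant = plant
        t = (k + 1) * frame_period
        frames.append(render_frame(scene, sensor, t, frame_index=k))
    return frames


# ---------------------------------------------------------------------------
# Validation rig
# ---------------------------------------------------------------------------

@dataclass
class ValidationRig:
    """Bench target emulating a patient: a temperature-controlled plate.

    The square plate is divided into a 3x3 grid of zones; per-zone offsets
    model residual non-uniformity of the real aluminium surface.  The rig's
    own thermometer reads ``plate_temp``.
    """

    plate_temp: float = 37.0
    zone_offsets: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3)))
    plate_origin: tuple[int, int] = (12, 12)
    plate_size: int = 9            # pixels per side, multiple of 3
    uniformity_bound: float = 0.5  # deg C

    def __post_init__(self) -> None:
        self.zone_offsets = np.asarray(self.zone_offsets, dtype=float)
        if self.zone_offsets.shape != (3, 3):
            raise ConfigurationError("zone_offsets must be 3x3")
        if np.abs(self.zone_offsets).max() > self.uniformity_bound:
            raise ConfigurationError("zone offset exceeds uniformity bound")
        if self.plate_size % 3 != 0:
            raise ConfigurationError("plate_size must be divisible by 3")
        r0, c0 = self.plate_origin
        if not (0 <= r0 and r0 + self.plate_size <= GRID_ROWS
                and 0 <= c0 and c0 + self.plate_size <= GRID_COLS):
            raise ConfigurationError("plate block outside grid")

    def true_patch(self) -> np.ndarray:
        """Plate-sized temperature block: plate_temp + per-zone offsets."""
        z = self.plate_size // 3
        return self.plate_temp + np.kron(self.zone_offsets, np.ones((z, z)))

    def mask(self) -> np.ndarray:
        m = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
        r0, c0 = self.plate_origin
        m[r0:r0 + self.plate_size, c0:c0 + self.plate_size] = True
        return m


def render_validation_plate(rig: ValidationRig, sensor: SensorModel,
                            scene: ThermalScene | None = None,
                            timestamp: float = 0.0,
                            frame_index: int = 0) -> ThermalFrame:
    """Render the validation plate (over *scene*'s background if given)."""
    base = scene if scene is not None else ThermalScene()
    true = base.true_field()
    r0, c0 = rig.plate_origin
    true[r0:r0 + rig.plate_size, c0:c0 + rig.plate_size] = rig.true_patch()
    raw = sensor.observe(true, frame_index)
    return ThermalFrame(values=raw, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def frames_to_dataframe(frames: Sequence[ThermalFrame]) -> pd.DataFrame:
    """Long-form table: one row per pixel, columns frame_index,row,col,value."""
    records = []
    for k, f in enumerate(frames):
        rr, cc = np.mgrid[0:GRID_ROWS, 0:GRID_COLS]
        records.append(pd.DataFrame({
            "frame_index": k,
            "row": rr.ravel(),
            "col": cc.ravel(),
            "value": f.values.ravel(),
        }))
    return pd.concat(records, ignore_index=True)


def save_frames_csv(frames: Sequence[ThermalFrame], path) -> None:
    frames_to_dataframe(frames).to_csv(path, index=False)


def save_frames_npz(frames: Sequence[ThermalFrame], path) -> None:
    np.savez(path,
             values=np.stack([f.values for f in frames]),
             timestamps=np.array([f.timestamp for f in frames]))


def load_frames_npz(path) -> list[ThermalFrame]:
    with np.load(path) as data:
        return [ThermalFrame(values=v, timestamp=float(t))
                for v, t in zip(data["values"], data["timestamps"])]
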