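"""Self-calibrating non-contact temperature measurement.

The measurement method: during warm-up the two Peltier reference patches are
the only things changing temperature in the field of view, so they are
located by per-pixel temperature *rise* between the start and the end of the
warm-up.  Each frame, a two-point (affine) calibration line is fitted through
the thermopile's raw readings of the two references against their contact
thermometers; the patient is the hottest pixel outside the (dilated)
reference regions; the mean of its 3x3 neighbourhood is pushed through the
calibration line.  An affine sensor error (gain/offset) is cancelled exactly
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .sim import (
    GRID_COLS,
    GRID_ROWS,
    ConfigurationError,
    PIDState,
    SensorModel,
    ThermalFrame,
    ValidationRig,
    default_scene,
    render_validation_plate,
    simulate_warmup,
)


class ReferencesNotFound(RuntimeError):
    """Raised when warm-up fluctuation analysis cannot find two references."""


class AmbiguousReferences(RuntimeError):
    """Raised when the two candidate reference regions touch."""


class DegenerateCalibration(ValueError):
    """Raised when the two raw anchors coincide or invert."""


@dataclass
class PeltierRegions:
    """Detected reference regions and the pixels excluded from patient search."""

    low_pixels: np.ndarray     # boolean grid
    high_pixels: np.ndarray    # boolean grid
    exclusion_mask: np.ndarray  # boolean grid, regions dilated by margin
    ref_low: float
    ref_high: float

    def __post_init__(self) -> None:
        if not (self.low_pixels.any() and self.high_pixels.any()):
            raise ReferencesNotFound("empty reference region")
        if (self.low_pixels & self.high_pixels).any():
            raise AmbiguousReferences("reference regions overlap")
        if not self.ref_low < self.ref_high:
            raise DegenerateCalibration("ref_low must be below ref_high")


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine raw -> corrected map, exact at both reference anchors."""

    slope: float
    intercept: float

    def apply(self, raw: float) -> float:
        return self.slope * raw + self.intercept


@dataclass
class PatientReading:
    """One corrected patient temperature."""

    pixel: tuple[int, int]
    raw_mean: float
    corrected: float
    timestamp: float


def detect_peltier_regions(warmup_frames: list[ThermalFrame],
                           ref_low: float, ref_high: float,
                           window: int = 5,
                           margin: int = 1,
                           threshold: float | None = None) -> PeltierRegions:
    """Locate the two reference patches from warm-up temperature rise.

    Per pixel, the rise score is ``mean(last window frames) - mean(first
    window frames)``.  Pixels scoring above the threshold (default: half the
    smaller setpoint rise above the ambient estimated from the first frame's
    median) are grouped into 4-connected components; the two largest become
    the regions, with the hotter one (by final-window mean) assigned
    ``ref_high``.  The exclusion mask is both regions dilated by *margin*.
    """
    if len(warmup_frames) < 10:
        raise ReferencesNotFound("need at least 10 warm-up frames")
    if not ref_low < ref_high:
        raise DegenerateCalibration("ref_low must be below ref_high")
    stack = np.stack([f.values for f in warmup_frames])
    early = stack[:window].mean(axis=0)
    late = stack[-window:].mean(axis=0)
    rise = late - early
    if threshold is None:
        ambient_est = float(np.median(stack[0]))
        threshold = 0.5 * (ref_low - ambient_est)
        if threshold <= 0:
            raise ReferencesNotFound(
                "low reference not above estimated ambient")
    candidates = rise > threshold
    labels, n = ndimage.label(candidates)  # 4-connectivity by default
    if n < 2:
        raise ReferencesNotFound(
            f"found {n} fluctuating region(s); expected 2")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.argsort(sizes)[-2:] + 1
    region_a = labels == keep[0]
    region_b = labels == keep[1]
    # Touching regions (even diagonally) make the assignment ambiguous.
    if (ndimage.binary_dilation(region_a, structure=np.ones((3, 3)))
            & region_b).any():
        raise AmbiguousReferences("candidate reference regions touch")
    mean_a = late[region_a].mean()
    mean_b = late[region_b].mean()
    low, high = (region_a, region_b) if mean_a < mean_b else (region_b, region_a)
    exclusion = ndimage.binary_dilation(
        low | high, structure=np.ones((3, 3)), iterations=margin)
    return PeltierRegions(low_pixels=low, high_pixels=high,
                          exclusion_mask=exclusion,
                          ref_low=ref_low, ref_high=ref_high)


def fit_calibration(raw_low: float, ref_low: float,
                    raw_high: float, ref_high: float) -> CalibrationCurve:
    """Two-point affine fit through (raw_low, ref_low) and (raw_high, ref_high)."""
    if raw_high == raw_low:
        raise DegenerateCalibration("raw anchors coincide")
    slope = (ref_high - ref_low) / (raw_high - raw_low)
    if slope <= 0:
        raise DegenerateCalibration("inverted references (slope <= 0)")
    intercept = ref_low - slope * raw_low
    return CalibrationCurve(slope=slope, intercept=intercept)


def calibrate_frame(frame: ThermalFrame, regions: PeltierRegions
                    ) -> CalibrationCurve:
    """Per-frame recalibration: anchor raw values are the region means."""
    raw_low = float(frame.values[regions.low_pixels].mean())
    raw_high = float(frame.values[regions.high_pixels].mean())
    return fit_calibration(raw_low, regions.ref_low, raw_high, regions.ref_high)


def locate_patient(frame: ThermalFrame, exclusion_mask: np.ndarray
                   ) -> tuple[int, int]:
    """Hottest non-excluded pixel; ties broken by smallest row-major index."""
    masked = np.where(exclusion_mask, -np.inf, frame.values)
    if not np.isfinite(masked).any():
        raise ValueError("all pixels excluded")
    flat = int(np.argmax(masked))  # argmax returns the first (row-major) max
    return (flat // GRID_COLS, flat % GRID_COLS)


def neighborhood_mean(values: np.ndarray, pixel: tuple[int, int]) -> float:
    """Mean of the 3x3 window at *pixel*, intersected with the grid."""
    r, c = pixel
    if not (0 <= r < GRID_ROWS and 0 <= c < GRID_COLS):
        raise ValueError("pixel outside grid")
    window = values[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
    return float(window.mean())


def patient_temperature(frame: ThermalFrame, pixel: tuple[int, int],
                        curve: CalibrationCurve) -> PatientReading:
    """Average the patient pixel's 3x3 neighbourhood, then correct it."""
    raw_mean = neighborhood_mean(frame.values, pixel)
    return PatientReading(pixel=pixel, raw_mean=raw_mean,
                          corrected=curve.apply(raw_mean),
                          timestamp=frame.timestamp)


def _smoothed(values: np.ndarray) -> np.ndarray:
    """3x3-neighbourhood-mean field with the same border handling as
    :func:`neighborhood_mean` (window intersected with the grid)."""
    ones = np.ones_like(values)
    ksum = ndimage.uniform_filter(values, size=3, mode="constant") * 9.0
    kcnt = ndimage.uniform_filter(ones, size=3, mode="constant") * 9.0
    return ksum / kcnt


def measure_patient(frame: ThermalFrame, regions: PeltierRegions,
                    curve: CalibrationCurve | None = None) -> PatientReading:
    """Full single-frame measurement used by the campaign and the monitor.

    The patient pixel is located on the 3x3-mean smoothed frame (robust to a
    flat hottest object: the winner's window then lies inside the object),
    and the standard 3x3 average at that pixel is corrected by the per-frame
    calibration.
    """
    if curve is None:
        curve = calibrate_frame(frame, regions)
    smooth = _smoothed(frame.values)
    pixel = locate_patient(ThermalFrame(values=smooth,
                                        timestamp=frame.timestamp),
                           regions.exclusion_mask)
    return patient_temperature(frame, pixel, curve)


# ---------------------------------------------------------------------------
# Validation campaign
# ---------------------------------------------------------------------------

@dataclass
class ValidationRecord:
    measured: float
    validation: float

    @property
    def error(self) -> float:
        return abs(self.measured - self.validation)


@dataclass
class CampaignConfig:
    """Knobs for a simulated bench validation campaign."""

    warmup_duration: float = 120.0
    frame_period: float = 1.0
    ref_bias_low: float = 0.0    # contact-thermometer bias, |bias| <= 1 C
    ref_bias_high: float = 0.0
    zone_offsets: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    pid: PIDState = field(default_factory=PIDState)

    def __post_init__(self) -> None:
        if max(abs(self.ref_bias_low), abs(self.ref_bias_high)) > 1.0:
            raise ConfigurationError("reference bias must lie within +-1 C")


def run_validation_campaign(validation_temps: list[float],
                            sensor: SensorModel,
                            repetitions: int = 1,
                            config: CampaignConfig | None = None,
                            ) -> list[ValidationRecord]:
    """Simulate the full bench protocol for each plate temperature.

    For each setting (times *repetitions*): warm the references up from
    ambient, self-detect them, present the plate, measure with per-frame
    recalibration, and record (measured, validation, |error|).
    """
    cfg = config if config is not None else CampaignConfig()
    for t in validation_temps:
        if not (30.0 <= t <= 42.0):
            raise ConfigurationError(f"validation temp {t} outside [30, 42] C")
    records: list[ValidationRecord] = []
    for rep in range(repetitions):
        for i, temp in enumerate(validation_temps):
            run_sensor = SensorModel(
                gain=sensor.gain, offset=sensor.offset,
                noise_sd=sensor.noise_sd,
                seed=int(np.random.SeedSequence(
                    [int(sensor.seed), rep, i]).generate_state(1)[0] % 2**31))
            scene = default_scene()
            frames = simulate_warmup(scene, run_sensor, cfg.warmup_duration,
                                     cfg.frame_period, pid=cfg.pid)
            # Contact thermometers read the (settled) plant truth plus bias.
            truth_low = scene.peltier_patches[0].plant.temp
            truth_high = scene.peltier_patches[1].plant.temp
            regions = detect_peltier_regions(
                frames,
                ref_low=truth_low + cfg.ref_bias_low,
                ref_high=truth_high + cfg.ref_bias_high)
            rig = ValidationRig(plate_temp=temp, zone_offsets=cfg.zone_offsets)
            frame = render_validation_plate(
                rig, run_sensor, scene=scene,
                timestamp=cfg.warmup_duration + 1.0,
                frame_index=len(frames))
            reading = measure_patient(frame, regions)
            records.append(ValidationRecord(measured=reading.corrected,
                                            validation=temp))
    return records


def campaign_to_dataframe(records: list[ValidationRecord]) -> pd.DataFrame:
    """Bench-table-shaped output: measured_C, validation_C, error_C."""
    return pd.DataFrame(
        [(r.measured, r.validation, r.error) for r in records],
        columns=["measured_C", "validation_C", "error_C"])
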