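"""Thermal scene simulator: sensor model, PID plant, warm-up, validation rig."""

import math

import numpy as np
import pytest

from thermocough.thermal import sim
from thermocough.thermal.sim import (
    ConfigurationError,
    Face,
    PeltierPatch,
    PeltierPlant,
    PIDState,
    SensorModel,
    ThermalScene,
    ValidationRig,
)


class TestRenderFrame:
    def test_identity_sensor_uniform_scene(self):
        scene = ThermalScene(ambient_temp=30.0)
        frame = sim.render_frame(scene, SensorModel(), timestamp=0.0)
        assert np.all(frame.values == 30.0)

    def test_frame_shape_is_24_by_32(self):
        frame = sim.render_frame(ThermalScene(), SensorModel(), 0.0)
        assert frame.values.shape == (24, 32)

    def test_affine_sensor_face_pixels(self):
        # gain 0.95, offset -1.2: a 37 C face must read 0.95*37 - 1.2 = 33.95
        scene = ThermalScene(face=Face(center=(16, 16), radius=3, temp=37.0))
        sensor = SensorModel(gain=0.95, offset=-1.2)
        frame = sim.render_frame(scene, sensor, 0.0)
        face_mask = scene.face.mask()
        assert np.allclose(frame.values[face_mask], 33.95)
        assert np.allclose(frame.values[~face_mask], 0.95 * 22.0 - 1.2)

    def test_patch_outside_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalScene(peltier_patches=[
                PeltierPatch(origin=(22, 30), height=4, width=4)])

    def test_overlapping_patches_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalScene(peltier_patches=[
                PeltierPatch(origin=(4, 4), height=4, width=4),
                PeltierPatch(origin=(6, 6), height=4, width=4)])

    def test_face_temperature_range_enforced(self):
        with pytest.raises(ConfigurationError):
            ThermalScene(face=Face(center=(10, 10), radius=2, temp=45.0))


class TestPlant:
    def test_equilibrium_at_zero_duty(self):
        plant = PeltierPlant(temp=22.0, ambient=22.0)
        for _ in range(100):
            plant = plant.step(0.0, 0.5)
        assert plant.temp == pytest.approx(22.0, abs=1e-12)

    def test_open_loop_matches_analytic_exponential(self):
        # Independent closed form: T(t) = T_inf + (T0 - T_inf) e^{-k_loss t}
        plant = PeltierPlant(temp=22.0, ambient=22.0)
        duty, dt = 0.64, 0.5
        t_inf = 22.0 + plant.k_heat * duty / plant.k_loss
        p = plant
        for k in range(1, 1201):
            p = p.step(duty, dt)
            expected = t_inf + (22.0 - t_inf) * math.exp(-plant.k_loss * k * dt)
            assert abs(p.temp - expected) < 1e-6

    def test_steady_state_formula(self):
        plant = PeltierPlant()
        assert plant.steady_state(0.64) == pytest.approx(22 + 0.5 * 0.64 / 0.02)


class TestPID:
    def test_zero_error_gives_zero_pd_contribution(self):
        plant = PeltierPlant(temp=38.0, setpoint=38.0)
        pid = PIDState(ki=0.0)  # isolate P and D terms
        duty, _, _ = sim.step_pid(plant, pid, 38.0)
        assert duty == 0.0

    def test_duty_clamped_to_unit_interval(self):
        plant = PeltierPlant(temp=22.0)
        duty, _, _ = sim.step_pid(plant, PIDState(), 38.0)
        assert duty == 1.0

    def test_non_finite_gain_rejected(self):
        with pytest.raises(ConfigurationError):
            PIDState(kp=float("nan"))

    @pytest.mark.parametrize("setpoint", [33.0, 38.0])
    def test_converges_within_tenth_degree_after_300s(self, setpoint):
        df = sim.simulate_plant(setpoint, 600.0)
        tail = df[df.time_s > 300.0]
        assert (tail.temp_C - setpoint).abs().max() <= 0.1

    def test_converged_duty_matches_closed_form_steady_state(self):
        # After settling, the duty must be the one whose open-loop steady
        # state equals the setpoint: d = k_loss (sp - ambient) / k_heat.
        df = sim.simulate_plant(38.0, 600.0)
        plant = PeltierPlant()
        final_duty = df.duty.iloc[-1]
        assert plant.steady_state(final_duty) == pytest.approx(38.0, abs=0.1)


class TestWarmup:
    def test_patch_means_reach_setpoints_in_two_minutes(self):
        scene = sim.default_scene()
        frames = sim.simulate_warmup(scene, SensorModel(), duration=120.0)
        last = frames[-1].values
        low = last[scene.peltier_patches[0].rows, scene.peltier_patches[0].cols]
        high = last[scene.peltier_patches[1].rows, scene.peltier_patches[1].cols]
        assert abs(low.mean() - 33.0) < 0.2
        assert abs(high.mean() - 38.0) < 0.2

    def test_zero_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.simulate_warmup(sim.default_scene(), SensorModel(), 0.0)

    def test_fixed_seed_reproduces_sequence_bytewise(self):
        runs = []
        for _ in range(2):
            scene = sim.default_scene()
            frames = sim.simulate_warmup(
                scene, SensorModel(noise_sd=0.3, seed=7), duration=30.0)
            runs.append(b"".join(f.values.tobytes() for f in frames))
        assert runs[0] == runs[1]

    def test_frames_are_chronological(self):
        frames = sim.simulate_warmup(sim.default_scene(), SensorModel(), 20.0)
        times = [f.timestamp for f in frames]
        assert times == sorted(times) and len(set(times)) == len(times)


class TestValidationRig:
    def test_uniform_plate_reads_plate_temp(self):
        rig = ValidationRig(plate_temp=37.81)
        frame = sim.render_validation_plate(rig, SensorModel())
        assert np.allclose(frame.values[rig.mask()], 37.81)

    def test_zone_offsets_reproduced_per_zone(self):
        offsets = np.linspace(-0.1, 0.1, 9).reshape(3, 3)
        rig = ValidationRig(plate_temp=37.0, zone_offsets=offsets)
        frame = sim.render_validation_plate(
            rig, SensorModel(noise_sd=0.02, seed=3))
        z = rig.plate_size // 3
        r0, c0 = rig.plate_origin
        for i in range(3):
            for j in range(3):
                block = frame.values[r0 + i * z:r0 + (i + 1) * z,
                                     c0 + j * z:c0 + (j + 1) * z]
                assert block.mean() == pytest.approx(
                    37.0 + offsets[i, j], abs=0.05)

    def test_background_is_ambient(self):
        rig = ValidationRig(plate_temp=37.0)
        frame = sim.render_validation_plate(rig, SensorModel())
        assert np.all(frame.values[~rig.mask()] == 22.0)

    def test_offset_beyond_uniformity_bound_rejected(self):
        with pytest.raises(ConfigurationError):
            ValidationRig(zone_offsets=np.full((3, 3), 0.8))

    def test_plate_outside_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ValidationRig(plate_origin=(20, 28))


class TestSerialization:
    def test_csv_long_form_schema(self, tmp_path):
        frames = sim.simulate_warmup(sim.default_scene(), SensorModel(), 3.0)
        path = tmp_path / "frames.csv"
        sim.save_frames_csv(frames, path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["frame_index", "row", "col", "value"]
        assert len(df) == len(frames) * 24 * 32

    def test_npz_roundtrip_bit_exact(self, tmp_path):
        frames = sim.simulate_warmup(
            sim.default_scene(), SensorModel(noise_sd=0.1, seed=1), 5.0)
        path = tmp_path / "frames.npz"
        sim.save_frames_npz(frames, path)
        loaded = sim.load_frames_npz(path)
        assert all(np.array_equal(a.values, b.values)
                   and a.timestamp == b.timestamp
                   for a, b in zip(frames, loaded))
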