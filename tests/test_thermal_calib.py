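"""Two-point calibration, reference self-detection, patient measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermocough.thermal import calib, sim
from thermocough.thermal.calib import (
    AmbiguousReferences,
    CampaignConfig,
    DegenerateCalibration,
    ReferencesNotFound,
    fit_calibration,
)
from thermocough.thermal.reference_table import reference_validation_table
from thermocough.thermal.sim import SensorModel, ThermalFrame


@pytest.fixture(scope="module")
def clean_warmup():
    """Noise-free warm-up with known patch geometry."""
    scene = sim.default_scene()
    frames = sim.simulate_warmup(scene, SensorModel(), 120.0)
    return scene, frames


class TestDetectRegions:
    def test_noise_free_recovery_is_exact(self, clean_warmup):
        scene, frames = clean_warmup
        regions = calib.detect_peltier_regions(frames, 33.0, 38.0)
        assert np.array_equal(regions.low_pixels,
                              scene.peltier_patches[0].mask())
        assert np.array_equal(regions.high_pixels,
                              scene.peltier_patches[1].mask())

    def test_exclusion_mask_covers_dilated_regions(self, clean_warmup):
        _, frames = clean_warmup
        regions = calib.detect_peltier_regions(frames, 33.0, 38.0)
        both = regions.low_pixels | regions.high_pixels
        assert (regions.exclusion_mask & both).sum() == both.sum()
        assert regions.exclusion_mask.sum() > both.sum()  # margin added

    def test_static_scene_has_no_references(self):
        scene = sim.ThermalScene()
        frames = [sim.render_frame(scene, SensorModel(), float(t))
                  for t in range(20)]
        with pytest.raises(ReferencesNotFound):
            calib.detect_peltier_regions(frames, 33.0, 38.0)

    def test_too_few_frames_rejected(self, clean_warmup):
        _, frames = clean_warmup
        with pytest.raises(ReferencesNotFound):
            calib.detect_peltier_regions(frames[:5], 33.0, 38.0)

    def test_noisy_detection_jaccard(self, clean_warmup):
        scene, _ = clean_warmup
        noisy = sim.simulate_warmup(sim.default_scene(),
                                    SensorModel(noise_sd=0.2, seed=11), 120.0)
        regions = calib.detect_peltier_regions(noisy, 33.0, 38.0)
        for detected, patch in [(regions.low_pixels, scene.peltier_patches[0]),
                                (regions.high_pixels, scene.peltier_patches[1])]:
            truth = patch.mask()
            jaccard = (detected & truth).sum() / (detected | truth).sum()
            assert jaccard >= 0.8

    def test_touching_components_ambiguous(self):
        # Two hot blocks separated by one diagonal pixel: distinct
        # 4-connected components that are 8-adjacent.
        base = np.full((24, 32), 22.0)
        hot = base.copy()
        hot[5:8, 5:8] += 10
        hot[8:11, 8:11] += 10
        frames = ([ThermalFrame(values=base, timestamp=t) for t in range(10)]
                  + [ThermalFrame(values=hot, timestamp=10 + t)
                     for t in range(10)])
        with pytest.raises(AmbiguousReferences):
            calib.detect_peltier_regions(frames, 33.0, 38.0)


class TestFitCalibration:
    @pytest.mark.parametrize("anchors,slope,intercept", [
        ((31.0, 33.0, 36.0, 38.0), 1.0, 2.0),
        ((33.0, 33.0, 38.0, 38.0), 1.0, 0.0),   # raw == ref: identity
    ])
    def test_known_anchor_fits(self, anchors, slope, intercept):
        curve = fit_calibration(*anchors)
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept)
        assert curve.apply(anchors[0]) == pytest.approx(anchors[1])

    def test_inverts_sensor_affine_map(self):
        # Anchors measured through raw = g*T + b must fit the inverse map.
        g, b = 0.93, 1.7
        curve = fit_calibration(g * 33 + b, 33.0, g * 38 + b, 38.0)
        assert curve.slope == pytest.approx(1 / g, abs=1e-9)
        assert curve.intercept == pytest.approx(-b / g, abs=1e-9)

    def test_coincident_anchors_degenerate(self):
        with pytest.raises(DegenerateCalibration):
            fit_calibration(35.0, 33.0, 35.0, 38.0)

    def test_inverted_references_rejected(self):
        with pytest.raises(DegenerateCalibration):
            fit_calibration(36.0, 33.0, 31.0, 38.0)

    @settings(derandomize=True, max_examples=200)
    @given(r_l=st.floats(20, 35), gap=st.floats(0.5, 15),
           t_l=st.floats(25, 35), t_gap=st.floats(0.5, 10))
    def test_exact_at_both_anchors(self, r_l, gap, t_l, t_gap):
        r_h, t_h = r_l + gap, t_l + t_gap
        curve = fit_calibration(r_l, t_l, r_h, t_h)
        assert curve.apply(r_l) == pytest.approx(t_l, abs=1e-12)
        assert curve.apply(r_h) == pytest.approx(t_h, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(20, 45), dx=st.floats(1e-6, 5))
    def test_correction_strictly_increasing(self, x, dx):
        curve = fit_calibration(31.0, 33.0, 36.0, 38.5)
        assert curve.apply(x + dx) > curve.apply(x)


class TestLocatePatient:
    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        no_exclusion = np.zeros((24, 32), dtype=bool)
        for _ in range(1000):
            values = rng.normal(30, 3, size=(24, 32))
            frame = ThermalFrame(values=values, timestamp=0.0)
            r, c = calib.locate_patient(frame, no_exclusion)
            # independent brute-force scan
            best, best_val = None, -np.inf
            for i in range(24):
                for j in range(32):
                    if values[i, j] > best_val:
                        best, best_val = (i, j), values[i, j]
            assert (r, c) == best

    def test_hot_pixel_found(self):
        values = np.full((24, 32), 30.0)
        values[10, 5] = 38.0
        frame = ThermalFrame(values=values, timestamp=0.0)
        assert calib.locate_patient(frame, np.zeros((24, 32), bool)) == (10, 5)

    def test_excluded_maximum_skipped(self):
        values = np.full((24, 32), 30.0)
        values[3, 3] = 40.0    # inside exclusion
        values[15, 20] = 38.0  # the admissible patient
        mask = np.zeros((24, 32), bool)
        mask[0:6, 0:6] = True
        frame = ThermalFrame(values=values, timestamp=0.0)
        assert calib.locate_patient(frame, mask) == (15, 20)

    def test_uniform_frame_tie_breaks_row_major(self):
        frame = ThermalFrame(values=np.full((24, 32), 30.0), timestamp=0.0)
        assert calib.locate_patient(frame, np.zeros((24, 32), bool)) == (0, 0)

    def test_all_excluded_is_error(self):
        frame = ThermalFrame(values=np.full((24, 32), 30.0), timestamp=0.0)
        with pytest.raises(ValueError):
            calib.locate_patient(frame, np.ones((24, 32), bool))


class TestPatientTemperature:
    def test_uniform_frame_identity_curve(self):
        frame = ThermalFrame(values=np.full((24, 32), 37.0), timestamp=0.0)
        curve = calib.CalibrationCurve(slope=1.0, intercept=0.0)
        assert calib.patient_temperature(frame, (12, 16), curve
                                         ).corrected == pytest.approx(37.0)

    def test_center_hotter_than_ring(self):
        values = np.full((24, 32), 30.0)
        values[9:12, 9:12] = 37.0
        values[10, 10] = 38.0
        frame = ThermalFrame(values=values, timestamp=0.0)
        curve = calib.CalibrationCurve(slope=1.0, intercept=0.0)
        reading = calib.patient_temperature(frame, (10, 10), curve)
        assert reading.raw_mean == pytest.approx((38 + 8 * 37) / 9)
        assert reading.corrected == pytest.approx(37.111, abs=1e-3)

    def test_corner_window_uses_four_cells(self):
        values = np.zeros((24, 32))
        values[0, 0], values[0, 1], values[1, 0], values[1, 1] = 1, 2, 3, 4
        frame = ThermalFrame(values=values, timestamp=0.0)
        curve = calib.CalibrationCurve(slope=1.0, intercept=0.0)
        assert calib.patient_temperature(frame, (0, 0), curve
                                         ).raw_mean == pytest.approx(2.5)

    def test_pixel_outside_grid_rejected(self):
        frame = ThermalFrame(values=np.zeros((24, 32)), timestamp=0.0)
        curve = calib.CalibrationCurve(slope=1.0, intercept=0.0)
        with pytest.raises(ValueError):
            calib.patient_temperature(frame, (24, 0), curve)


class TestEndToEnd:
    @pytest.mark.parametrize("gain,offset", [(0.95, -1.2), (1.05, 0.8)])
    def test_affine_error_cancelled_to_1e9(self, gain, offset):
        """Parameter recovery: a pure gain/offset error is exactly invertible."""
        scene = sim.default_scene()
        sensor = SensorModel(gain=gain, offset=offset)
        frames = sim.simulate_warmup(scene, sensor, 120.0)
        regions = calib.detect_peltier_regions(
            frames, ref_low=scene.peltier_patches[0].plant.temp,
            ref_high=scene.peltier_patches[1].plant.temp)
        rig = sim.ValidationRig(plate_temp=37.3)
        frame = sim.render_validation_plate(rig, sensor, scene=scene,
                                            frame_index=len(frames))
        reading = calib.measure_patient(frame, regions)
        assert abs(reading.corrected - 37.3) < 1e-9

    def test_campaign_noise_free_affine_errors_vanish(self):
        records = calib.run_validation_campaign(
            [36.5, 37.5, 38.5], SensorModel(gain=0.95, offset=-1.2))
        assert max(r.error for r in records) < 1e-9

    def test_campaign_monte_carlo_mean_error(self):
        temps = reference_validation_table()["validation_C"].tolist()
        records = calib.run_validation_campaign(
            temps, SensorModel(gain=0.97, offset=0.5, noise_sd=0.2, seed=42))
        assert np.mean([r.error for r in records]) <= 0.4

    def test_campaign_rejects_out_of_range_temps(self):
        with pytest.raises(sim.ConfigurationError):
            calib.run_validation_campaign([50.0], SensorModel())

    def test_campaign_csv_shape(self, tmp_path):
        records = calib.run_validation_campaign([37.0], SensorModel())
        df = calib.campaign_to_dataframe(records)
        path = tmp_path / "campaign.csv"
        df.to_csv(path, index=False)
        assert path.read_text().splitlines()[0] == \
            "measured_C,validation_C,error_C"

    def test_reference_bias_beyond_spec_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            CampaignConfig(ref_bias_low=1.5)


class TestReferenceTable:
    def test_error_column_is_absolute_difference(self):
        df = reference_validation_table()
        recomputed = (df.measured_C - df.validation_C).abs()
        assert (recomputed - df.error_C).abs().max() < 0.005
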