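"""Concentration quantitation: calibration, ratios, partitioning, time lapse."""

import numpy as np
import pytest

import dropletlab as dl
from dropletlab.quant import CalibrationError


def _curve(slope=100.0, intercept=0.0, cf=1.0):
    conc = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
    return dl.fit_calibration(conc, slope * conc + intercept, correction_factor=cf)


class TestFitCalibration:
    def test_perfect_line_recovered_exactly(self):
        curve = _curve(slope=100.0, intercept=5.0)
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_synthetic_field_round_trip(self):
        conc = [0.0, 1.0, 2.0, 4.0]
        fields = dl.make_calibration_fields(conc, slope=100.0, background=3.0)
        means = [f.data.mean() for f in fields]
        curve = dl.fit_calibration(conc, means)
        assert curve.slope == pytest.approx(100.0, rel=1e-3)

    def test_saturating_response_fails_linearity_gate(self):
        conc = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        intens = 100.0 * conc - 8.0 * conc**2  # saturation curvature
        with pytest.raises(CalibrationError, match="R²"):
            dl.fit_calibration(conc, intens)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValueError):
            dl.fit_calibration([1.0, 1.0, 1.0], [10.0, 11.0, 12.0])


class TestDropletConcentration:
    def test_intensity_at_intercept_maps_to_zero(self):
        curve = _curve(intercept=0.0)
        assert dl.droplet_concentration(0.0, curve, dl.LabeledSample(0.1)) == pytest.approx(
            0.0, abs=1e-9)

    def test_unit_algebra(self):
        curve = _curve(slope=100.0)
        conc = dl.droplet_concentration(100.0, curve, dl.LabeledSample(0.1))
        assert conc == pytest.approx(10.0)

    def test_correction_factor_divides(self):
        curve = _curve(slope=100.0, cf=0.73)
        conc = dl.droplet_concentration(73.0, curve, dl.LabeledSample(0.1))
        assert conc == pytest.approx(10.0)

    def test_below_intercept_clips_to_zero_with_warning(self):
        curve = _curve(intercept=10.0)
        with pytest.warns(UserWarning, match="below"):
            assert dl.droplet_concentration(5.0, curve, dl.LabeledSample(1.0)) == 0.0

    def test_condition_mismatch_refused(self):
        conc = np.array([0.0, 1.0, 2.0, 4.0])
        curve = dl.fit_calibration(conc, 100 * conc, crowder_condition="5% PEG")
        with pytest.raises(ValueError, match="override"):
            dl.droplet_concentration(50.0, curve, dl.LabeledSample(0.1), condition="15% PEG")

    def test_linearity_above_intercept(self):
        curve = _curve(slope=50.0, intercept=10.0)
        s = dl.LabeledSample(0.2)
        c1 = dl.droplet_concentration(110.0, curve, s)
        c2 = dl.droplet_concentration(210.0, curve, s)
        assert c2 == pytest.approx(2 * c1)

    def test_full_image_round_trip_recovers_ground_truth(self):
        """A droplet painted from a 100 µM / 10% labeled / 0.73-corrected
        scenario quantifies back to 100 µM within 2%."""
        slope, lf, cf, conc_true = 200.0, 0.1, 0.73, 100.0
        curve = _curve(slope=slope, cf=cf)
        amp = slope * conc_true * lf * cf
        spec = dl.DropletSpec(center_xy=(40.0, 40.0), radius=14.0,
                              channel_amplitudes=(amp, amp / 2))
        img, _ = dl.make_droplet_image(
            dl.SceneSpec(image_shape=(81, 81), droplets=(spec,), background_level=25.0))
        table = dl.concentrations_from_scene(
            img, (curve, _curve(slope=slope)), (dl.LabeledSample(lf), dl.LabeledSample(lf)))
        assert table["conc_ch1_um"][0] == pytest.approx(conc_true, rel=0.02)


class TestMolarRatio:
    def test_equal_concentrations(self):
        res = dl.molar_ratio([5.0, 5.0], [5.0, 5.0])
        assert res.mean == 1.0 and res.n_excluded == 0

    def test_zero_denominator_excluded_and_counted(self):
        res = dl.molar_ratio([10.0, 10.0, 10.0], [1.0, 0.0, 2.0])
        assert res.n_excluded == 1
        assert res.ratios.tolist() == [10.0, 5.0]

    def test_common_gain_invariance(self):
        a = np.array([3.0, 6.0])
        b = np.array([1.0, 2.0])
        assert dl.molar_ratio(7.3 * a, 7.3 * b).mean == dl.molar_ratio(a, b).mean

    def test_dense_phase_ten_to_one_through_full_pipeline(self):
        """Scenes painted at 10:1 monomer stoichiometry with the green/red
        quantum-yield corrections quantify back to 10:1 within 5%."""
        slope_g, slope_r, lf = 200.0, 150.0, 0.1
        conc = np.array([0.0, 20.0, 40.0, 80.0, 120.0])
        cal_g = dl.fit_calibration(conc, slope_g * conc, correction_factor=0.73)
        conc_r = np.array([0.0, 4.0, 8.0, 12.0, 18.0])
        cal_r = dl.fit_calibration(conc_r, slope_r * conc_r, correction_factor=1.43)
        amp1 = slope_g * 1000.0 * lf * 0.73
        amp2 = slope_r * 100.0 * lf * 1.43
        droplets = tuple(
            dl.DropletSpec(center_xy=c, radius=r, channel_amplitudes=(amp1 * s, amp2 * s))
            for c, r, s in [((40.0, 40.0), 14.0, 1.0), ((120.0, 45.0), 12.0, 0.9),
                            ((45.0, 120.0), 15.0, 1.1), ((115.0, 115.0), 13.0, 1.0)]
        )
        img, _ = dl.make_droplet_image(
            dl.SceneSpec(image_shape=(160, 160), droplets=droplets, background_level=30.0))
        table = dl.concentrations_from_scene(
            img, (cal_g, cal_r), (dl.LabeledSample(lf), dl.LabeledSample(lf)))
        res = dl.molar_ratio(table["conc_ch1_um"], table["conc_ch2_um"])
        assert res.mean == pytest.approx(10.0, rel=0.05)


class TestPartitionCoefficient:
    def test_equal_intensities_give_unity(self):
        assert dl.partition_coefficient(100.0, 100.0) == 1.0

    def test_gain_invariance(self):
        assert dl.partition_coefficient(70.0, 100.0) == dl.partition_coefficient(700.0, 1000.0)

    def test_light_below_background_rejected(self):
        with pytest.raises(ValueError):
            dl.partition_coefficient(50.0, 10.0, background=20.0)

    def test_depleted_tracer_scene_round_trip(self):
        """A tracer at dense:light = 0.7 returns K = 0.7 through segmentation."""
        img, truth = dl.make_partition_scene(
            (120, 120), (60.0, 60.0), 20.0, dense_intensity=70.0, light_intensity=100.0)
        region = dl.segment_scene(img)[0]
        from scipy import ndimage as ndi
        eroded = ndi.binary_erosion(region.mask, iterations=2)
        dense = float(img.plane(0)[1][eroded].mean())
        outside = ~ndi.binary_dilation(region.mask, iterations=4)
        light = float(np.median(img.plane(0)[1][outside]))
        k = dl.partition_coefficient(dense, light)
        assert k == pytest.approx(truth["k_true"], abs=0.05)


class TestLightPhase:
    def test_division_by_labeled_fraction(self):
        conc = [0.0, 1.0, 2.0]
        reads = [0.0, 50.0, 100.0]
        assert dl.light_phase_concentration(50.0, conc, reads, 0.16) == pytest.approx(6.25)

    def test_zero_reading_zero_intercept(self):
        assert dl.light_phase_concentration(0.0, [0.0, 1.0], [0.0, 10.0], 1.0) == 0.0

    def test_plate_round_trip_at_known_concentration(self):
        # standards: reading = 40 * labeled conc; sample at 10 µM total, 16% labeled
        conc = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        reads = 40.0 * conc
        reading = 40.0 * (10.0 * 0.16)
        assert dl.light_phase_concentration(reading, conc, reads, 0.16) == pytest.approx(
            10.0, rel=0.01)

    def test_out_of_range_reading_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            dl.light_phase_concentration(1000.0, [0.0, 1.0], [0.0, 10.0], 1.0)


class TestCompositionTraces:
    def test_constant_no_bleach_is_flat(self):
        t = np.arange(0.0, 10.0)
        norm1, ratio = dl.composition_traces(t, np.full(10, 50.0), np.full(10, 25.0))
        assert np.allclose(norm1, 1.0)
        assert np.allclose(ratio, 0.5)

    def test_bleach_only_scenario_corrects_flat(self):
        t = np.arange(0.0, 100.0, 5.0)
        k1, k2 = 0.003, 0.001
        y1 = 80.0 * np.exp(-k1 * t)
        y2 = 20.0 * np.exp(-k2 * t)
        norm1, ratio = dl.composition_traces(t, y1, y2, k1, k2)
        assert np.allclose(norm1, 1.0)
        assert np.allclose(ratio, 0.25)

    def test_invasion_scenario_recovered_under_bleaching(self):
        """Channel 2 ramping 5x and channel 1 declining 10% are recovered
        within 3% after correcting the imposed photobleaching."""
        t = np.linspace(0.0, 900.0, 60)
        true1 = 100.0 * (1.0 - 0.1 * t / t[-1])
        true2 = 10.0 * (1.0 + 4.0 * t / t[-1])
        k1, k2 = 0.0012, 0.0005
        obs1 = true1 * np.exp(-k1 * t)
        obs2 = true2 * np.exp(-k2 * t)
        norm1, ratio = dl.composition_traces(t, obs1, obs2, k1, k2)
        assert np.allclose(norm1, true1 / true1[0], rtol=0.03)
        assert np.allclose(ratio, true2 / true1, rtol=0.03)

    def test_empty_timelapse_rejected(self):
        with pytest.raises(ValueError, match="t0"):
            dl.composition_traces([], [], [])
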