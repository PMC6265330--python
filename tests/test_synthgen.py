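"""Generator outputs must satisfy their defining formulas exactly."""

import numpy as np
import pytest

import dropletlab as dl
from dropletlab.synthgen import make_phase_grid


class TestDropletImages:
    def test_empty_noiseless_scene_is_constant_background(self):
        scene = dl.SceneSpec(image_shape=(32, 48), background_level=17.0)
        img, truth = dl.make_droplet_image(scene)
        assert img.data.shape == (2, 32, 48)
        assert np.all(img.data == 17.0)
        assert truth.empty

    def test_noiseless_image_matches_analytic_profile_pixelwise(self):
        """Independent re-evaluation of background + amplitude*g(r) per pixel."""
        spec = dl.DropletSpec(
            center_xy=(21.0, 19.0), radius=10.0,
            channel_amplitudes=(5.0, 3.0),
            shell_factor_per_channel=(1.4, 0.8),
            shell_width_fraction=0.2, edge_softness=2.0,
        )
        scene = dl.SceneSpec(image_shape=(41, 41), droplets=(spec,), background_level=2.0)
        img, _ = dl.make_droplet_image(scene)
        for c in range(2):
            for y in range(41):
                for x in range(41):
                    r = np.hypot(x - 21.0, y - 19.0)
                    inner = 10.0 * 0.8
                    g = 1.0 if r < inner else spec.shell_factor_per_channel[c]
                    ramp = np.clip((10.0 + 1.0 - r) / 2.0, 0.0, 1.0)
                    expected = 2.0 + spec.channel_amplitudes[c] * g * ramp
                    assert img.data[c, y, x] == pytest.approx(expected, abs=1e-12)

    def test_equal_shell_factors_give_constant_interior_ratio(self):
        spec = dl.DropletSpec(center_xy=(40.0, 40.0), radius=18.0,
                              channel_amplitudes=(700.0, 350.0))
        img, _ = dl.make_droplet_image(dl.SceneSpec(image_shape=(81, 81), droplets=(spec,)))
        yy, xx = np.mgrid[0:81, 0:81]
        interior = np.hypot(xx - 40, yy - 40) < 15
        ratio = img.data[0][interior] / img.data[1][interior]
        assert np.allclose(ratio, 2.0)

    def test_azimuthal_shell_to_core_ratio_matches_shell_factor(self):
        """Rendered annulus/core two-channel ratio recovers the 1.3 factor to 2%."""
        spec = dl.DropletSpec(
            center_xy=(50.0, 50.0), radius=20.0,
            channel_amplitudes=(800.0, 600.0),
            shell_factor_per_channel=(1.3, 1.0), shell_width_fraction=0.15,
        )
        img, _ = dl.make_droplet_image(dl.SceneSpec(image_shape=(101, 101), droplets=(spec,)))
        yy, xx = np.mgrid[0:101, 0:101]
        r = np.hypot(xx - 50, yy - 50)
        core = r < 0.8 * 20
        shell = (r >= 0.85 * 20 + 1) & (r <= 20 - 1)  # clear of step and edge ramp
        ratio_core = img.data[0][core] / img.data[1][core]
        ratio_shell = img.data[0][shell] / img.data[1][shell]
        assert np.mean(ratio_shell) / np.mean(ratio_core) == pytest.approx(1.3, rel=0.02)

    def test_out_of_bounds_droplet_rejected(self):
        spec = dl.DropletSpec(center_xy=(5.0, 5.0), radius=10.0)
        with pytest.raises(ValueError, match="beyond"):
            dl.make_droplet_image(dl.SceneSpec(image_shape=(64, 64), droplets=(spec,)))

    def test_seed_determinism_and_noise_isolation(self):
        spec = dl.DropletSpec(center_xy=(30.0, 30.0), radius=10.0)
        kw = dict(image_shape=(64, 64), droplets=(spec,), noise_sigma=3.0)
        a, _ = dl.make_droplet_image(dl.SceneSpec(rng_seed=7, **kw))
        b, _ = dl.make_droplet_image(dl.SceneSpec(rng_seed=7, **kw))
        c, _ = dl.make_droplet_image(dl.SceneSpec(rng_seed=8, **kw))
        clean, _ = dl.make_droplet_image(dl.SceneSpec(rng_seed=7, noise_sigma=0.0,
                                                      image_shape=(64, 64), droplets=(spec,)))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        # differing seeds change only the noise: the noiseless part is shared
        assert np.allclose(a.data - (a.data - clean.data), c.data - (c.data - clean.data))

    def test_zstack_planes_shrink_spherically(self):
        spec = dl.DropletSpec(center_xy=(30.0, 30.0), radius=4.0, edge_softness=0.0)
        img, _ = dl.make_droplet_image(dl.SceneSpec(image_shape=(11, 61, 61), droplets=(spec,)))
        assert img.is_zstack and img.n_planes == 11
        mid_area = (img.plane(5)[0] > 0).sum()
        off_area = (img.plane(8)[0] > 0).sum()
        assert 0 < off_area < mid_area
        # plane beyond the sphere is empty
        assert (img.plane(0)[0] > 0).sum() == 0

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            dl.DropletSpec(center_xy=(0, 0), radius=-1.0)
        with pytest.raises(ValueError):
            dl.DropletSpec(center_xy=(0, 0), radius=5.0, shell_width_fraction=0.6)
        with pytest.raises(ValueError):
            dl.DropletSpec(center_xy=(0, 0), radius=5.0, channel_amplitudes=(-1.0, 1.0))


class TestBeads:
    @pytest.mark.parametrize("amps,expected", [((1.0, 1.0), 1.0), ((2.0, 1.0), 2.0)])
    def test_per_pixel_channel_ratio_inside_bead(self, amps, expected):
        img = dl.make_bead_image((81, 81), bead_radius=15.0, amplitudes=amps)
        yy, xx = np.mgrid[0:81, 0:81]
        inside = np.hypot(xx - 40, yy - 40) < 13
        assert np.allclose(img.data[0][inside] / img.data[1][inside], expected)


class TestFrapTraces:
    def test_model_values_at_landmarks(self):
        times = np.array([0.0, 14.3, 1430.0])
        tr = dl.make_frap_trace(0.0, 0.79, 14.3, times)
        assert tr.intensities[0] == pytest.approx(0.0)
        assert tr.intensities[1] == pytest.approx(0.79 / 2)
        assert tr.intensities[2] == pytest.approx(0.79 * 100 / 101)

    def test_midpoint_identity_generic(self):
        tr = dl.make_frap_trace(0.2, 0.9, 7.0, [0.0, 7.0])
        assert tr.intensities[1] == pytest.approx((0.2 + 0.9) / 2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            dl.make_frap_trace(0.0, 0.8, -1.0, [0.0, 1.0])
        with pytest.raises(ValueError):
            dl.make_frap_trace(0.9, 0.5, 10.0, [0.0, 1.0])  # i0 > i_inf

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValueError):
            dl.FrapTrace(np.array([0.0, 1.0, 1.0]), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            dl.FrapTrace(np.array([0.0, 1.0]), np.array([-0.1, 0.2]))


class TestDiffusionSimulator:
    def test_zero_mobile_fraction_gives_flat_trace(self):
        tr = dl.simulate_frap_diffusion(0.05, 5.0, 1.0, 0.0, np.arange(0.0, 10.0, 1.0),
                                        grid_step=0.25)
        assert np.allclose(tr.intensities, tr.intensities[0])
        assert tr.intensities[0] == pytest.approx(0.0)

    def test_fast_diffusion_plateaus_at_mobile_weighted_level(self):
        mf = 0.6
        tr = dl.simulate_frap_diffusion(100.0, 5.0, 1.0, mf, np.array([0.0, 5.0, 10.0]),
                                        grid_step=0.25)
        # equilibrated mobile pool refills the ROI up to mf*(1 - roi/disk area)
        expected = mf * (1.0 - (1.0 / 5.0) ** 2)
        assert tr.intensities[-1] == pytest.approx(expected, rel=0.02)

    def test_plateau_agrees_with_hyperbolic_model_when_matched(self):
        mf = 0.8
        sim = dl.simulate_frap_diffusion(0.2, 10.0, 1.0, mf, np.arange(0.0, 120.0, 1.0),
                                         grid_step=0.25)
        plateau = mf * (1.0 - (1.0 / 10.0) ** 2)
        matched = dl.make_frap_trace(0.0, plateau, 1.0, np.array([0.0, 1e6]))
        assert sim.intensities[-1] == pytest.approx(matched.intensities[-1], rel=0.02)

    def test_unstable_discretization_rejected_with_named_condition(self):
        with pytest.raises(ValueError, match="grid_step"):
            dl.simulate_frap_diffusion(0.05, 5.0, 0.5, 1.0, np.array([0.0, 1.0]),
                                       grid_step=1.0)

    def test_bleach_radius_must_fit_inside_droplet(self):
        with pytest.raises(ValueError, match="bleach_radius"):
            dl.simulate_frap_diffusion(0.05, 1.0, 2.0, 1.0, np.array([0.0, 1.0]))


class TestCalibrationFields:
    def test_means_are_linear_in_concentration(self):
        fields = dl.make_calibration_fields([0.0, 1.0, 2.0, 4.0], slope=100.0, background=7.0)
        means = [f.data.mean() for f in fields]
        assert means == pytest.approx([7.0, 107.0, 207.0, 407.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            dl.make_calibration_fields([-1.0, 1.0], slope=10.0)


class TestPhaseGrids:
    def test_subsaturated_grid_has_no_positives(self):
        grid, _ = make_phase_grid([1.0, 2.0], [1.0, 2.0], [0.0], lambda c: 50.0,
                                  steepness=1.0)
        assert not dl.classify_llps(grid["od340"].to_numpy()).any()

    def test_supersaturated_grid_is_all_positive(self):
        grid, _ = make_phase_grid([60.0, 80.0], [60.0, 80.0], [0.0], lambda c: 5.0,
                                  steepness=1.0)
        assert dl.classify_llps(grid["od340"].to_numpy()).all()

    def test_csat_model_must_be_non_increasing_in_crowder(self):
        with pytest.raises(ValueError, match="non-increasing"):
            make_phase_grid([1.0], [1.0], [0.0, 5.0], lambda c: 10.0 + c)
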