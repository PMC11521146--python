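"""Transport kernel: geometry, conservation, tallies, reweighting."""

import math

import numpy as np
import pytest

from tiltprobe.transport import (
    DetectionTally,
    FiberSpec,
    Medium,
    ProbeLayout,
    detect,
    launch_photons,
    propagate,
    reflectance_uncertainty,
    reweight_reflectance,
    sampling_depth_zv80,
)


class TestLayout:
    def test_overlapping_footprints_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ProbeLayout.linear([0.30, 0.35])

    def test_touching_footprints_allowed(self):
        ProbeLayout.linear([0.3, 0.4, 0.5])  # exactly one diameter apart

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            ProbeLayout.linear([0.0, 0.5])

    def test_invalid_fiber_rejected(self):
        with pytest.raises(ValueError):
            FiberSpec(tilt_deg=95.0)


class TestLaunch:
    def test_collimated_limit_points_down(self, case1_medium):
        layout = ProbeLayout.linear([0.5], tilt_deg=0.0, na=1e-6)
        _, dirs = launch_photons(layout, case1_medium, 1000, np.random.default_rng(0))
        np.testing.assert_allclose(dirs[:, 2], 1.0, atol=1e-6)

    def test_positions_inside_footprint(self, case1_medium):
        layout = ProbeLayout.linear([0.5])
        pos, _ = launch_photons(layout, case1_medium, 10_000, np.random.default_rng(0))
        assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= 0.05 + 1e-12)
        np.testing.assert_allclose(pos[:, 2], 0.0)

    @pytest.mark.parametrize("coupling,axis_angle", [("matched", 40.0), ("air", None)])
    def test_directions_within_cone(self, case1_medium, coupling, axis_angle):
        """All launch directions lie within asin(NA/n_in) of the tilted
        axis: the full tilt for matched coupling, the refracted tilt for
        air coupling."""
        tilt = 40.0
        layout = ProbeLayout.linear([0.5], tilt_deg=tilt)
        _, dirs = launch_photons(
            layout, case1_medium, 50_000, np.random.default_rng(1), coupling
        )
        if axis_angle is None:
            sin_in = math.sin(math.radians(tilt)) / case1_medium.n_in
            axis_angle = math.degrees(math.asin(sin_in))
        ax = np.array(
            [math.sin(math.radians(axis_angle)), 0, math.cos(math.radians(axis_angle))]
        )
        cos_cone = math.sqrt(1 - (0.4 / case1_medium.n_in) ** 2)
        assert np.all(dirs @ ax >= cos_cone - 1e-9)
        # the cone is actually filled, not collapsed on the axis
        assert (dirs @ ax).min() < cos_cone + 0.002


class TestDetect:
    def test_on_axis_exit_detected(self):
        layout = ProbeLayout.linear([0.5])
        assert detect((0.5, 0.0, 0.0), (0.0, 0.0, -1.0), layout) == 0

    def test_outside_footprint_not_detected(self):
        layout = ProbeLayout.linear([0.5])
        assert detect((0.61, 0.0, 0.0), (0.0, 0.0, -1.0), layout) is None

    def test_outside_cone_rejected_in_air(self):
        # 30 degrees off a perpendicular detector axis; NA 0.4 in air
        # accepts only ~23.6 degrees
        layout = ProbeLayout.linear([0.5])
        d = (math.sin(math.radians(30)), 0.0, -math.cos(math.radians(30)))
        assert detect((0.5, 0.0, 0.0), d, layout, coupling="air") is None
        d_ok = (math.sin(math.radians(20)), 0.0, -math.cos(math.radians(20)))
        assert detect((0.5, 0.0, 0.0), d_ok, layout, coupling="air") == 0

    def test_downward_direction_rejected(self):
        layout = ProbeLayout.linear([0.5])
        with pytest.raises(ValueError):
            detect((0.5, 0.0, 0.0), (0.0, 0.0, 1.0), layout)


class TestPropagate:
    def test_weight_accounting_closes(self, small_case1_tally):
        total = sum(small_case1_tally.conservation.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_roulette_net_is_small(self, small_case1_tally):
        # roulette is unbiased: its net weight creation/destruction is
        # zero-mean and should be far below the detected signal scale
        assert abs(small_case1_tally.conservation["roulette_net"]) < 1e-3

    def test_identical_seeds_reproduce_bitwise(self, case1_medium):
        layout = ProbeLayout.linear([0.3, 0.6])
        a = propagate(case1_medium, layout, 20_000, seed=9)
        b = propagate(case1_medium, layout, 20_000, seed=9)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        np.testing.assert_array_equal(a.ps, b.ps)
        np.testing.assert_array_equal(a.depth_hist, b.depth_hist)

    def test_no_unscattered_detections(self, small_case1_tally):
        np.testing.assert_array_equal(small_case1_tally.ps[:, 0], 0.0)
        np.testing.assert_array_equal(small_case1_tally.ps_counts[:, 0], 0.0)

    def test_reflectance_decreases_with_separation(self, small_case1_tally):
        r = small_case1_tally.reflectance
        assert np.all(np.diff(r) < 0)

    def test_zero_absorption_detects_roulette_free_weights(self, case1_medium):
        med0 = Medium(case1_medium.mu_s, 0.0, case1_medium.phase)
        layout = ProbeLayout.linear([0.3])
        tally = propagate(med0, layout, 30_000, seed=3, record_paths=True)
        # with mu_a = 0 and no roulette firing, every detected weight is
        # its (arc-fraction-scored) geometric weight <= 1
        assert np.all(tally.records["weight"] <= 1.0 + 1e-12)
        assert tally.conservation["absorbed"] == pytest.approx(0.0, abs=1e-12)

    def test_ring_scoring_agrees_with_direct_detection(self, case2_medium):
        """The ring-averaged estimator must agree with brute-force direct
        footprint detection within combined errors (same physics, lower
        variance)."""
        layout = ProbeLayout.linear([0.4])
        sym = propagate(case2_medium, layout, 150_000, seed=11)
        # tilting by an infinitesimal angle forces the direct path
        layout_d = ProbeLayout.linear([0.4], tilt_deg=1e-7)
        direct = propagate(case2_medium, layout_d, 1_500_000, seed=12)
        se = math.hypot(sym.reflectance_se[0], direct.reflectance_se[0])
        assert abs(sym.reflectance[0] - direct.reflectance[0]) < 3.5 * se

    def test_invalid_run_parameters_rejected(self, case1_medium):
        layout = ProbeLayout.linear([0.3])
        with pytest.raises(ValueError):
            propagate(case1_medium, layout, 0, seed=1)
        with pytest.raises(ValueError):
            propagate(case1_medium, layout, 100, seed=1, n_batches=0)
        with pytest.raises(ValueError):
            propagate(case1_medium, layout, 100, seed=1, coupling="vacuum")


class TestUncertainty:
    def test_standard_error_scales_with_photon_count(self, case1_medium):
        layout = ProbeLayout.linear([0.25])
        se = {}
        for n in (100_000, 400_000):
            t = propagate(case1_medium, layout, n, seed=21)
            se[n] = reflectance_uncertainty(t)[0]
        # doubling the budget four-fold halves the SE, within a loose band
        ratio = se[100_000] / se[400_000]
        assert 1.2 < ratio < 3.5

    def test_single_batch_rejected(self, case1_medium):
        layout = ProbeLayout.linear([0.3])
        t = propagate(case1_medium, layout, 10_000, seed=2, n_batches=1)
        with pytest.raises(ValueError):
            reflectance_uncertainty(t)

    def test_empty_detector_flagged(self, case1_medium):
        layout = ProbeLayout.linear([4.0])  # far detector, no signal expected
        t = propagate(case1_medium, layout, 500, seed=2)
        if t.reflectance[0] == 0:
            assert np.isnan(reflectance_uncertainty(t)[0])


class TestSamplingDepth:
    def _tally_with_hist(self, hist):
        n = len(hist)
        return DetectionTally(
            rhos=np.array([0.5]),
            n_photons=1,
            n_batches=2,
            reflectance=np.array([1.0]),
            reflectance_se=np.array([0.0]),
            ps=np.zeros((1, 4)),
            ps_counts=np.zeros((1, 4)),
            depth_hist=np.asarray(hist, dtype=float)[None, :],
            depth_bin=0.01,
            n_detected=np.array([1]),
            conservation={},
            seed=0,
        )

    def test_point_mass_depth(self):
        hist = np.zeros(600)
        hist[50] = 3.0  # all events in the bin covering 0.50-0.51 mm
        t = self._tally_with_hist(hist)
        assert sampling_depth_zv80(t, 0) == pytest.approx(0.508, abs=1e-9)

    def test_uniform_density_quantile(self):
        hist = np.ones(100)  # uniform on [0, 1] mm
        t = self._tally_with_hist(hist)
        assert sampling_depth_zv80(t, 0) == pytest.approx(0.8, abs=1e-9)

    def test_empty_histogram_rejected(self):
        t = self._tally_with_hist(np.zeros(10))
        with pytest.raises(ValueError):
            sampling_depth_zv80(t, 0)

    def test_depth_grows_with_separation(self, small_case1_tally):
        z1 = sampling_depth_zv80(small_case1_tally, 0)  # rho = 0.25
        z3 = sampling_depth_zv80(small_case1_tally, 2)  # rho = 0.75
        assert z3 > z1


class TestReweighting:
    def test_reweighted_matches_direct_absorption_run(self, case1_medium):
        """A mu_a = 0 run reweighted by exp(-mu_a L) must reproduce a
        direct mu_a > 0 run — the identity behind the LUT mu_a axis."""
        layout = ProbeLayout.linear([0.3, 0.6])
        med0 = Medium(case1_medium.mu_s, 0.0, case1_medium.phase)
        t0 = propagate(med0, layout, 400_000, seed=31, record_paths=True)
        r_rw, se_rw = reweight_reflectance(t0, case1_medium.mu_a)
        t1 = propagate(case1_medium, layout, 400_000, seed=32)
        for j in range(2):
            se = math.hypot(se_rw[j], t1.reflectance_se[j])
            assert abs(r_rw[j] - t1.reflectance[j]) < 3.5 * se

    def test_records_required(self, small_case1_tally):
        with pytest.raises(ValueError):
            reweight_reflectance(small_case1_tally, 0.5)
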