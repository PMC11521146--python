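"""LUT construction, cost minimization and noise robustness."""

import numpy as np
import pytest

from tiltprobe.config import make_fixtures
from tiltprobe.inversion import (
    LUT,
    add_noise,
    build_lut,
    cost,
    cost_surface_slice,
    estimation_error,
    invert,
    robustness_experiment,
)
from tiltprobe.transport import ProbeLayout


@pytest.fixture(scope="module")
def mini_lut():
    return make_fixtures(3)["mini_lut"]


@pytest.fixture(scope="module")
def small_lut():
    """Small transport-backed LUT around the case-1 neighbourhood."""
    layout = ProbeLayout.linear([0.4, 0.6, 0.8, 1.0])
    return build_lut(
        layout,
        mus_grid=np.linspace(1.0, 3.0, 5),
        gamma_grid=np.linspace(1.25, 1.75, 3),
        mua_grid=np.linspace(0.0, 0.6, 7),
        n_photons=100_000,
        seed=13,
    )


@pytest.fixture(scope="module")
def case1_truth(small_lut):
    """Independently seeded case-1 reflectance on the small_lut layout."""
    from tiltprobe.transport import Medium, propagate

    med = Medium.from_reduced(2.0, 1.5, 0.2)
    layout = ProbeLayout.linear([0.4, 0.6, 0.8, 1.0])
    return propagate(med, layout, 400_000, seed=99).reflectance


class TestCost:
    def test_zero_at_equality(self):
        assert cost([0.2, 0.1], [0.2, 0.1]) == 0.0

    def test_proportional_offset(self):
        r = np.array([0.2, 0.1, 0.05])
        assert cost(1.1 * r, r) == pytest.approx(0.1)

    def test_worked_example(self):
        # (0.05/0.2 + 0.02/0.1) / 2 fibers
        assert cost([0.25, 0.08], [0.2, 0.1]) == pytest.approx(0.225)

    def test_scale_invariance(self):
        r_sim = np.array([0.3, 0.12])
        r_exp = np.array([0.25, 0.15])
        assert cost(3.7 * r_sim, 3.7 * r_exp) == pytest.approx(cost(r_sim, r_exp))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            cost([0.1], [0.0])


class TestInvert:
    def test_exact_node_recovered(self, mini_lut):
        r = mini_lut.values[2, 4, 3]
        res = invert(mini_lut, r)
        assert res.index == (2, 4, 3)
        assert res.cost == pytest.approx(0.0, abs=1e-12)

    def test_detector_subset(self, mini_lut):
        r = mini_lut.values[1, 1, 1]
        res = invert(mini_lut, r, detectors=[0, 2])
        assert res.cost == pytest.approx(0.0, abs=1e-12)

    def test_invalid_nodes_excluded(self, mini_lut):
        lut = LUT(
            mini_lut.mus_grid,
            mini_lut.gamma_grid,
            mini_lut.mua_grid,
            mini_lut.rhos,
            mini_lut.values,
            mini_lut.se,
            np.zeros_like(mini_lut.valid),
            meta={},
        )
        with pytest.raises(ValueError, match="valid"):
            invert(lut, mini_lut.values[0, 0, 0])


class TestBuildLut:
    def test_reflectance_monotone_in_absorption(self, small_lut):
        v = small_lut.values[small_lut.valid]
        assert np.all(np.diff(v, axis=-2) <= 1e-15)

    def test_node_count_and_validity(self, small_lut):
        assert small_lut.values.shape == (5, 3, 7, 4)
        assert small_lut.valid.all()  # gamma <= 1.75 is representable at g1=0.9

    def test_infeasible_gamma_nodes_marked_invalid(self):
        layout = ProbeLayout.linear([0.4])
        lut = build_lut(
            layout,
            mus_grid=[1.0],
            gamma_grid=[1.5, 1.95],  # 1.95 > 1 + g1 is not representable
            mua_grid=[0.0, 0.5],
            n_photons=2_000,
            seed=1,
        )
        assert lut.valid[0, 0] and not lut.valid[0, 1]

    def test_round_trips_through_hdf5(self, small_lut, tmp_path):
        path = tmp_path / "lut.h5"
        small_lut.save(path)
        back = LUT.load(path)
        np.testing.assert_array_equal(back.values, small_lut.values)
        assert back.meta["seed"] == small_lut.meta["seed"]

    def test_noiseless_recovery_within_one_grid_step(self, small_lut, case1_truth):
        """Inverting an independently seeded case-1 reflectance recovers
        the truth to one grid step per axis."""
        res = invert(small_lut, case1_truth)
        steps = (
            np.diff(small_lut.mus_grid)[0],
            np.diff(small_lut.gamma_grid)[0],
            np.diff(small_lut.mua_grid)[0],
        )
        for est, tru, step in zip(res.estimate, (2.0, 1.5, 0.2), steps):
            assert abs(est - tru) <= step + 1e-9


class TestNoiseAndError:
    def test_estimation_error_definition(self):
        assert estimation_error((2.2, 1.5, 0.1), (2.0, 1.5, 0.2)) == pytest.approx(
            (0.1 + 0.0 + 0.5) / 3
        )

    def test_noise_is_positive_and_unbiased(self):
        rng = np.random.default_rng(0)
        r = np.array([1e-4, 5e-6])
        draws = np.array([add_noise(r, 0.10, rng) for _ in range(4000)])
        assert np.all(draws > 0)
        np.testing.assert_allclose(draws.mean(axis=0), r, rtol=0.02)
        np.testing.assert_allclose(draws.std(axis=0), 0.10 * r, rtol=0.1)


class TestRobustness:
    def test_noiseless_scan_recovers_immediately(self, mini_lut):
        truth_idx = (3, 2, 2)
        r = mini_lut.values[truth_idx]
        truth = (
            mini_lut.mus_grid[3],
            mini_lut.gamma_grid[2],
            mini_lut.mua_grid[2],
        )
        res = robustness_experiment(
            mini_lut, r, truth, rho_min=mini_lut.rhos[0], noise_frac=0.0, n_reps=2
        )
        assert res.rho_max == pytest.approx(mini_lut.rhos[0])
        np.testing.assert_allclose(res.mean_error, 0.0, atol=1e-12)

    def test_error_tends_down_as_detectors_accumulate(self, mini_lut):
        truth_idx = (3, 2, 2)
        r = mini_lut.values[truth_idx]
        truth = (
            mini_lut.mus_grid[3],
            mini_lut.gamma_grid[2],
            mini_lut.mua_grid[2],
        )
        res = robustness_experiment(
            mini_lut,
            r,
            truth,
            rho_min=mini_lut.rhos[0],
            noise_frac=0.10,
            n_reps=30,
            seed=4,
        )
        assert res.mean_error[-1] <= res.mean_error[0] + res.se_error[0]

    def test_unreachable_tolerance_reports_none(self, mini_lut):
        r = mini_lut.values[(3, 2, 2)]
        truth = (1e9, 1e9, 1e9)  # absurd truth: error can never be small
        res = robustness_experiment(
            mini_lut, r, truth, rho_min=mini_lut.rhos[0], n_reps=2
        )
        assert res.rho_max is None


class TestCostSurface:
    def test_minimum_matches_invert_at_fixed_gamma(self, mini_lut):
        r = mini_lut.values[2, 3, 1]
        c, _ = cost_surface_slice(mini_lut, r, mini_lut.gamma_grid[3])
        res = invert(mini_lut, r)
        if res.index[1] == 3:
            assert c.min() == pytest.approx(res.cost, abs=1e-12)
        assert c[2, 1] == pytest.approx(0.0, abs=1e-12)

    def test_more_detectors_shrink_the_low_cost_region(self, small_lut, case1_truth):
        """The low-cost valley of a single detector is at least as large
        as the multi-detector one: combining separations disambiguates
        the (mus', mu_a) trade-off."""
        _, mask_all = cost_surface_slice(small_lut, case1_truth, 1.5, contour=0.2)
        for d in range(len(small_lut.rhos)):
            _, mask_single = cost_surface_slice(
                small_lut, case1_truth, 1.5, detectors=[d], contour=0.2
            )
            assert mask_all.sum() <= mask_single.sum()

    def test_off_grid_gamma_rejected(self, mini_lut):
        with pytest.raises(ValueError):
            cost_surface_slice(mini_lut, mini_lut.values[0, 0, 0], 1.2345)
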