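"""Simulator self-consistency: closed forms, derivatives, regimes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from steer.evaluate import morans_i, row_standardize
from steer.graph import build_spatial_graph
from steer.simulate import (
    simulate_bifurcation,
    simulate_single_regime,
    simulate_spatial,
    solve_piecewise_kinetics,
)


class TestClosedForm:
    def test_steady_state_limits(self):
        u, s = solve_piecewise_kinetics([0, 100.0], [1.0], [1.0], [0.5],
                                        0.0, 0.0, np.array([100.0]))
        assert u[0] == pytest.approx(1.0, abs=1e-6)  # alpha/beta
        assert s[0] == pytest.approx(2.0, abs=1e-6)  # alpha/gamma

    def test_pure_decay_monotone_to_zero(self):
        t = np.linspace(0, 10, 50)
        u, _ = solve_piecewise_kinetics([0, 10.0], [0.0], [0.8], [0.4],
                                        5.0, 3.0, t)
        assert (np.diff(u) < 0).all()
        assert u[-1] < 0.01

    def test_matches_numerical_integration_on_random_schedule(self, rng):
        breaks = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 9.5, 3)), [10.0]])
        al = rng.uniform(0.5, 5, 4)
        be = rng.uniform(0.2, 1, 4)
        ga = rng.uniform(0.1, 0.7, 4)
        t_grid = np.linspace(0, 10, 40)
        u, s = solve_piecewise_kinetics(breaks, al, be, ga, 0.0, 0.0, t_grid)

        def rhs(t, y):
            i = min(np.searchsorted(breaks, t, side="right") - 1, 3)
            return [al[i] - be[i] * y[0], be[i] * y[0] - ga[i] * y[1]]

        sol = solve_ivp(rhs, [0, 10], [0, 0], t_eval=t_grid, method="RK45",
                        rtol=1e-10, atol=1e-12, max_step=0.05)
        np.testing.assert_allclose(u, sol.y[0], atol=1e-6)
        np.testing.assert_allclose(s, sol.y[1], atol=1e-6)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            solve_piecewise_kinetics([0, 1], [-1.0], [0.5], [0.3], 0, 0,
                                     np.array([0.5]))

    def test_equal_beta_gamma_perturbed_not_nan(self):
        u, s = solve_piecewise_kinetics([0, 5.0], [2.0], [0.5], [0.5], 0, 0,
                                        np.linspace(0, 5, 10))
        assert np.isfinite(u).all() and np.isfinite(s).all()


class TestDerivativeConsistency:
    def test_first_order_convergence_of_finite_differences(self):
        """d(U,S)/dt from finite differences matches the ODE right-hand side
        with error halving as the step halves."""
        breaks, al, be, ga = [0.0, 20.0], [3.0], [0.6], [0.3]

        def fd_error(dt):
            t = np.arange(0.5, 15, 0.37)
            u0, s0 = solve_piecewise_kinetics(breaks, al, be, ga, 0, 0, t)
            u1, s1 = solve_piecewise_kinetics(breaks, al, be, ga, 0, 0, t + dt)
            du_err = np.abs((u1 - u0) / dt - (al[0] - be[0] * u0))
            ds_err = np.abs((s1 - s0) / dt - (be[0] * u0 - ga[0] * s0))
            return du_err.max() + ds_err.max()

        e1, e2 = fd_error(0.1), fd_error(0.05)
        assert e2 < e1
        assert e2 / e1 == pytest.approx(0.5, abs=0.1)  # first order

    def test_truth_velocity_satisfies_ode_identity(self):
        _, truth = simulate_bifurcation(100, 30, noise="none", seed=5)
        np.testing.assert_allclose(
            truth.v_u, truth.alpha - truth.beta * truth.U_clean, atol=1e-12)
        np.testing.assert_allclose(
            truth.v_s, truth.beta * truth.U_clean - truth.gamma * truth.S_clean,
            atol=1e-12)


class TestBifurcation:
    def test_noiseless_data_equals_clean_trajectories(self):
        data, truth = simulate_bifurcation(80, 20, noise="none", seed=3)
        np.testing.assert_array_equal(data.U, truth.U_clean)
        np.testing.assert_array_equal(data.S, truth.S_clean)

    def test_same_seed_reproduces_exactly(self):
        d1, t1 = simulate_bifurcation(50, 20, seed=9)
        d2, t2 = simulate_bifurcation(50, 20, seed=9)
        np.testing.assert_array_equal(d1.U, d2.U)
        np.testing.assert_array_equal(t1.true_time, t2.true_time)

    def test_four_regimes_present_with_defaults(self):
        _, truth = simulate_bifurcation(400, 40, seed=0)
        assert len(np.unique(truth.regime_labels)) == 4
        # regimes are the cross of time phase and lineage
        pre = truth.true_time < 0.4
        assert set(truth.regime_labels[pre]) == {0, 1}
        assert set(truth.regime_labels[~pre]) == {2, 3}

    def test_circular_genes_close_their_loop(self):
        """After induction and repression, u returns near its start."""
        _, truth = simulate_bifurcation(300, 40, noise="none", seed=7)
        circ = np.nonzero(truth.pattern_per_gene == "circular")[0]
        early = truth.true_time < 0.03
        late = truth.true_time > 0.97
        for j in circ[:5]:
            u_start = truth.U_clean[early, j].mean()
            u_end = truth.U_clean[late, j].mean()
            span = truth.U_clean[:, j].max()
            assert abs(u_end - u_start) < 0.25 * span

    def test_pattern_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_bifurcation(10, 10, pattern_mix=(0.5, 0.5, 0.5, 0.0))

    def test_branching_genes_diverge_only_after_split(self):
        _, truth = simulate_bifurcation(500, 40, noise="none", seed=2)
        j = np.nonzero(truth.pattern_per_gene == "branching")[0][0]
        pre = truth.true_time < 0.35
        post = truth.true_time > 0.8
        for phase, expect_equal in ((pre, True), (post, False)):
            l1 = truth.alpha[phase & (truth.lineage_labels == "L1"), j]
            l2 = truth.alpha[phase & (truth.lineage_labels == "L2"), j]
            if expect_equal:
                assert abs(l1.mean() - l2.mean()) < 1e-9
            else:
                assert abs(l1.mean() - l2.mean()) > 0.1


class TestSpatial:
    def test_bilinear_time_field_spatially_autocorrelated(self):
        data, truth = simulate_spatial("bilinear", (12, 12), 30, seed=1)
        g = build_spatial_graph(data.spatial_coords, k=4)
        W = row_standardize(g.adjacency)
        assert morans_i(truth.true_time, W) > 0.5

    def test_multi_radial_single_center_is_radial(self):
        data, truth = simulate_spatial("multi_radial", (11, 11), 20,
                                       n_centers=1, seed=2)
        center = data.spatial_coords[np.argmin(truth.true_time)]
        d = np.linalg.norm(data.spatial_coords - center, axis=1)
        # time increases monotonically with distance from the single center
        order = np.argsort(d)
        assert (np.diff(truth.true_time[order]) >= -1e-9).all()

    def test_regions_have_distinct_rates(self):
        _, truth = simulate_spatial("bilinear", (10, 10), 20, noise="none", seed=4)
        r0 = truth.regime_labels == 0
        assert not np.allclose(truth.alpha[r0][0], truth.alpha[~r0][0])


def test_single_regime_constant_rates():
    _, truth = simulate_single_regime(100, 10, seed=6)
    for mat in (truth.alpha, truth.beta, truth.gamma):
        assert (np.ptp(mat, axis=0) == 0).all()  # constant per gene
    assert len(np.unique(truth.regime_labels)) == 1
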