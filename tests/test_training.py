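"""Training orchestration: forward pairs, dynamical loss, fit contracts."""

import dataclasses

import numpy as np
import pytest

from steer._autograd import Tensor
from steer.graph import build_expression_graph
from steer.simulate import simulate_bifurcation, solve_piecewise_kinetics
from steer.training import (
    TrainConfig,
    dynamical_loss,
    dynamical_loss_pairs,
    fit,
    forward_neighbors,
    forward_pairs,
    load_model,
    predict,
    save_model,
    total_objective,
)

SMOKE_CONFIG = dict(
    epochs=(2, 2, 2), K=2, hidden=16, d_z=8, heads=1, n_hvg=40,
    pca_dim=10, k_expr=8, expert_hidden=8, time_hidden=8, gate_hidden=8,
    min_u=1.0, r_min=0.05,
)


@pytest.fixture(scope="module")
def smoke_data():
    data, truth = simulate_bifurcation(60, 40, seed=4)
    return data, truth


class TestForwardNeighbors:
    def test_maximal_cell_has_empty_forward_set(self):
        g = build_expression_graph(np.arange(5.0)[:, None], k=2)
        t = np.array([0.1, 0.2, 0.5, 0.7, 0.9])
        assert forward_neighbors(g, t, 4, dt_max=0.5) == set()

    def test_two_cell_edge(self):
        g = build_expression_graph(np.array([[0.0], [1.0]]), k=1)
        t = np.array([0.1, 0.2])
        assert forward_neighbors(g, t, 0) == {1}
        assert forward_neighbors(g, t, 1) == set()

    def test_matches_brute_force_scan(self, rng):
        g = build_expression_graph(rng.normal(size=(20, 3)), k=5)
        t = rng.uniform(size=20)
        A = g.adjacency.toarray()
        pi, pj = forward_pairs(g, t, dt_max=0.2)
        got = set(zip(pi.tolist(), pj.tolist()))
        want = {
            (i, j)
            for i in range(20)
            for j in np.nonzero(A[i])[0]
            if 0 < t[j] - t[i] <= 0.2
        }
        assert got == want


class TestDynamicalLoss:
    def test_steady_state_pair_has_zero_residual(self):
        # alpha = beta*U and beta*U = gamma*S, expression unchanged
        U = np.array([[2.0], [2.0]])
        S = np.array([[1.0], [1.0]])
        alpha = np.array([[1.0], [1.0]])
        beta = np.array([[0.5], [0.5]])
        gamma = np.array([[1.0], [1.0]])
        t = np.array([0.1, 0.2])
        loss = dynamical_loss_pairs(U, S, alpha, beta, gamma, t,
                                    np.array([0]), np.array([1]))
        assert loss.data == pytest.approx(0.0, abs=1e-15)

    def test_single_pair_arithmetic(self):
        # worked example: rates at the fixed point, dt = 0.1
        U = np.array([[2.0], [2.0]])
        S = np.array([[1.0], [1.0]])
        loss = dynamical_loss_pairs(
            U, S, np.full((2, 1), 1.0), np.full((2, 1), 0.5),
            np.full((2, 1), 1.0), np.array([0.0, 0.1]),
            np.array([0]), np.array([1]))
        assert loss.data == pytest.approx(0.0, abs=1e-15)

    def test_first_order_convergence_on_noiseless_trajectory(self):
        """With true rates plugged in, halving the time step shrinks the
        forward-difference residual."""
        al, be, ga = 3.0, 0.6, 0.3

        def loss_at(dt):
            t = np.arange(0.3, 10, 0.9)
            u0, s0 = solve_piecewise_kinetics([0, 20.0], [al], [be], [ga], 0, 0, t)
            u1, s1 = solve_piecewise_kinetics([0, 20.0], [al], [be], [ga], 0, 0, t + dt)
            n = len(t)
            U = np.concatenate([u0, u1])[:, None]
            S = np.concatenate([s0, s1])[:, None]
            tt = np.concatenate([t, t + dt])
            pair_i = np.arange(n)
            pair_j = np.arange(n) + n
            a = np.full((2 * n, 1), al)
            b = np.full((2 * n, 1), be)
            g = np.full((2 * n, 1), ga)
            return dynamical_loss_pairs(U, S, a, b, g, tt, pair_i, pair_j).data

        l1, l2 = loss_at(0.2), loss_at(0.1)
        assert l2 < l1
        assert l2 / l1 < 0.5  # squared residuals of a first-order scheme

    def test_no_forward_pairs_warns_and_returns_zero(self):
        g = build_expression_graph(np.array([[0.0], [1.0]]), k=1)
        t = np.array([0.5, 0.5])  # no strict ordering
        with pytest.warns(UserWarning):
            val = dynamical_loss(np.ones((2, 1)), np.ones((2, 1)),
                                 np.ones((2, 1)), np.ones((2, 1)),
                                 np.ones((2, 1)), t, g)
        assert val == 0.0


class TestObjective:
    def test_all_zero_weights_give_zero(self):
        cfg = TrainConfig(lambda_recon=0, lambda_smooth=0, lambda_dir=0,
                          lambda_cut=0, lambda_dyn=0)
        terms = {k: Tensor(1.0) for k in ("recon", "smooth", "dir", "cut", "dyn")}
        total, _ = total_objective(terms, cfg, stage=3)
        assert total.data == 0.0

    def test_stage1_is_reconstruction_only(self):
        cfg = TrainConfig()
        terms = {"recon": Tensor(2.0), "smooth": Tensor(99.0)}
        total, breakdown = total_objective(terms, cfg, stage=1)
        assert total.data == pytest.approx(cfg.lambda_recon * 2.0)
        assert list(breakdown) == ["recon"]

    def test_breakdown_sums_to_total(self, rng):
        cfg = TrainConfig()
        terms = {k: Tensor(float(v)) for k, v in
                 zip(("recon", "smooth", "dir", "cut", "dyn"),
                     rng.uniform(0.1, 2, 5))}
        total, breakdown = total_objective(terms, cfg, stage=3)
        assert sum(breakdown.values()) == pytest.approx(total.data, abs=1e-8)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda_dyn=-1.0)


class TestFitContracts:
    def test_smoke_fit_sets_all_stage_flags(self, smoke_data):
        data, _ = smoke_data
        model = fit(data, TrainConfig(**SMOKE_CONFIG))
        assert model.stage_flags == (True, True, True)
        assert model.t.min() == 0.0 and model.t.max() == 1.0  # min–max normalized
        assert model.W.shape[1] == 2
        np.testing.assert_allclose(model.W.sum(axis=1), 1.0, atol=1e-9)
        assert (model.alpha > 0).all() and (model.gamma > 0).all()

    def test_same_seed_reproduces_parameters(self, smoke_data):
        data, _ = smoke_data
        m1 = fit(data, TrainConfig(**SMOKE_CONFIG, seed=3))
        m2 = fit(data, TrainConfig(**SMOKE_CONFIG, seed=3))
        np.testing.assert_array_equal(m1.t, m2.t)
        for p1, p2 in zip(m1.gaae.parameters(), m2.gaae.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_objective_mostly_non_increasing(self, smoke_data):
        data, _ = smoke_data
        cfg = TrainConfig(**{**SMOKE_CONFIG, "epochs": (25, 25, 25)})
        model = fit(data, cfg)
        drops = 0
        comparisons = 0
        for stage in (1, 2, 3):
            totals = [e["total"] for e in model.log if e["stage"] == stage]
            drops += sum(1 for a, b in zip(totals, totals[1:]) if b <= a + 1e-9)
            comparisons += len(totals) - 1
        assert drops / comparisons >= 0.9


class TestPersistence:
    def test_save_load_round_trip_identical_predictions(self, smoke_data, tmp_path):
        data, _ = smoke_data
        model = fit(data, TrainConfig(**SMOKE_CONFIG))
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        for p1, p2 in zip(model.gaae.parameters(), loaded.gaae.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)
        re = predict(loaded, data)
        np.testing.assert_allclose(re.t, model.t, atol=1e-12)
        np.testing.assert_allclose(re.alpha, model.alpha, atol=1e-12)

    def test_missing_gene_raises_explicit_error(self, smoke_data, tmp_path):
        data, _ = smoke_data
        model = fit(data, TrainConfig(**SMOKE_CONFIG))
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        smaller = data.subset_genes(np.arange(data.n_genes - 1))
        with pytest.raises(ValueError, match="lacks genes"):
            predict(loaded, smaller)
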