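"""Evaluation metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
import scipy.sparse as sp

from steer.evaluate import (
    ari,
    cbdir,
    local_coherence,
    morans_i,
    row_standardize,
    time_correlation,
    velocity_cosine,
)
from steer.graph import build_expression_graph


class TestVelocityCosine:
    def test_identical_vectors_give_one(self, rng):
        v = rng.normal(size=(6, 4))
        vals, mean, excluded = velocity_cosine(v, v.copy())
        np.testing.assert_allclose(vals, 1.0)
        assert mean == pytest.approx(1.0)
        assert excluded == 0

    def test_opposite_vectors_give_minus_one(self, rng):
        v = rng.normal(size=(6, 4))
        _, mean, _ = velocity_cosine(v, -v)
        assert mean == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        vp, vt = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        vals, _, _ = velocity_cosine(vp, vt, axis="cells")
        for i in range(5):
            want = vp[i] @ vt[i] / (np.linalg.norm(vp[i]) * np.linalg.norm(vt[i]))
            assert vals[i] == pytest.approx(want, abs=1e-12)
        gvals, _, _ = velocity_cosine(vp, vt, axis="genes")
        for j in range(4):
            want = vp[:, j] @ vt[:, j] / (
                np.linalg.norm(vp[:, j]) * np.linalg.norm(vt[:, j]))
            assert gvals[j] == pytest.approx(want, abs=1e-12)

    def test_zero_vectors_excluded_and_counted(self, rng):
        vp = rng.normal(size=(4, 3))
        vp[2] = 0.0
        vt = rng.normal(size=(4, 3))
        vals, _, excluded = velocity_cosine(vp, vt)
        assert excluded == 1
        assert np.isnan(vals[2])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            velocity_cosine(np.zeros((3, 2)), np.ones((3, 2)))


class TestTimeCorrelation:
    def test_monotone_transform_gives_one(self, rng):
        t = rng.uniform(size=30)
        assert time_correlation(np.exp(3 * t), t) == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self, rng):
        t = rng.uniform(size=30)
        assert time_correlation(-t, t) == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        # oracle: Pearson correlation of average ranks
        a = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 2.0, 5.0, 4.0, 4.0])

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            sx = x[order]
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        want = np.corrcoef(ra, rb)[0, 1]
        assert time_correlation(a, b) == pytest.approx(want, abs=1e-12)

    def test_constant_input_reported_undefined(self):
        assert np.isnan(time_correlation(np.ones(5), np.arange(5.0)))


@pytest.fixture
def labeled_fixture(rng):
    coords = np.vstack([rng.normal(0, 0.5, (6, 2)), rng.normal(1.0, 0.5, (6, 2))])
    graph = build_expression_graph(coords, k=4)
    labels = np.array(["A"] * 6 + ["B"] * 6)
    S = rng.uniform(0, 5, size=(12, 4))
    v = rng.normal(size=(12, 4))
    return coords, graph, labels, S, v


class TestCbdir:
    def test_velocity_equal_to_displacement_scores_one(self, labeled_fixture):
        _, graph, labels, S, _ = labeled_fixture
        A = graph.adjacency.toarray()
        v = np.zeros_like(S)
        for i in np.nonzero(labels == "A")[0]:
            js = [j for j in np.nonzero(A[i])[0] if labels[j] == "B"]
            if js:
                v[i] = (S[js] - S[i]).mean(axis=0)
        _, overall = cbdir(v, S, graph, labels, [("A", "B")])
        assert overall == pytest.approx(1.0)

    def test_orthogonal_velocity_scores_zero(self):
        coords = np.array([[0.0, 0], [1, 0]])
        graph = build_expression_graph(coords, k=1)
        labels = np.array(["A", "B"])
        S = np.array([[0.0, 0.0], [1.0, 0.0]])
        v = np.array([[0.0, 1.0], [0.0, 0.0]])  # orthogonal to displacement
        _, overall = cbdir(v, S, graph, labels, [("A", "B")])
        assert overall == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, labeled_fixture):
        _, graph, labels, S, v = labeled_fixture
        scores, overall = cbdir(v, S, graph, labels, [("A", "B"), ("B", "A")])
        A = graph.adjacency.toarray()
        for a, b in [("A", "B"), ("B", "A")]:
            cell_scores = []
            for i in np.nonzero(labels == a)[0]:
                js = [j for j in np.nonzero(A[i])[0] if labels[j] == b]
                if not js:
                    continue
                disp = (S[js] - S[i]).mean(axis=0)
                cell_scores.append(v[i] @ disp /
                                   (np.linalg.norm(v[i]) * np.linalg.norm(disp)))
            assert scores[(a, b)] == pytest.approx(np.mean(cell_scores), abs=1e-10)
        assert overall == pytest.approx(np.mean(list(scores.values())), abs=1e-10)

    def test_missing_transition_reported(self, labeled_fixture):
        _, graph, labels, S, v = labeled_fixture
        labels = labels.copy()
        labels[labels == "B"] = "A"  # no B cells at all
        scores, overall = cbdir(v, S, graph, labels, [("A", "B")])
        assert np.isnan(scores[("A", "B")])
        assert np.isnan(overall)


class TestLocalCoherence:
    def test_identical_velocities_give_one(self, rng):
        graph = build_expression_graph(rng.normal(size=(8, 2)), k=3)
        v = np.tile([[1.0, 2.0, 0.5]], (8, 1))
        _, mean = local_coherence(v, graph)
        assert mean == pytest.approx(1.0)

    def test_alternating_velocities_on_bipartite_chain(self):
        coords = np.arange(6.0)[:, None]
        graph = build_expression_graph(coords, k=1)  # chain
        v = np.array([[1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0]])
        _, mean = local_coherence(v, graph)
        assert mean == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        graph = build_expression_graph(rng.normal(size=(9, 3)), k=3)
        v = rng.normal(size=(9, 5))
        vals, _ = local_coherence(v, graph)
        A = graph.adjacency.toarray()
        for i in range(9):
            js = np.nonzero(A[i])[0]
            want = np.mean([
                v[i] @ v[j] / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]))
                for j in js
            ])
            assert vals[i] == pytest.approx(want, abs=1e-12)

    def test_scale_invariance(self, rng):
        graph = build_expression_graph(rng.normal(size=(8, 2)), k=2)
        v = rng.normal(size=(8, 3))
        scale = rng.uniform(0.5, 3.0, size=(8, 1))
        _, m1 = local_coherence(v, graph)
        _, m2 = local_coherence(v * scale, graph)
        assert m1 == pytest.approx(m2, abs=1e-12)


class TestMoransI:
    @staticmethod
    def rook_2x2():
        # cells 0..3 in a 2x2 grid, rook adjacency
        W = np.zeros((4, 4))
        for a, b in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            W[a, b] = W[b, a] = 1
        return sp.csr_matrix(W)

    def test_checkerboard_is_minus_one(self):
        # values {1,0,0,1}: hand computation gives ΣW=8, cross=-2, denom=1
        x = np.array([1.0, 0.0, 0.0, 1.0])
        assert morans_i(x, self.rook_2x2()) == pytest.approx(-1.0)

    def test_smooth_gradient_on_chain_near_one(self):
        n = 50
        W = sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1]).tocsr()
        x = np.linspace(0, 1, n)
        got = morans_i(x, W)
        # brute-force double-sum oracle
        xc = x - x.mean()
        Wd = W.toarray()
        want = (n / Wd.sum()) * (xc @ Wd @ xc) / (xc @ xc)
        assert got == pytest.approx(want, abs=1e-12)
        assert got > 0.9

    def test_permutation_null_mean(self, rng):
        n = 30
        W = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        x = rng.normal(size=n)
        vals = [morans_i(rng.permutation(x), W) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(4), self.rook_2x2())

    def test_row_standardized_weights_bound(self, rng):
        W = row_standardize(self.rook_2x2())
        x = rng.normal(size=4)
        assert -1.0 - 1e-9 <= morans_i(x, W) <= 1.0 + 1e-9


def brute_force_ari(a, b):
    """Pair-counting definition of the adjusted Rand index."""
    from math import comb

    n = len(a)
    labels_a, labels_b = np.unique(a), np.unique(b)
    C = np.array([[np.sum((a == la) & (b == lb)) for lb in labels_b]
                  for la in labels_a])
    sum_ij = sum(comb(int(x), 2) for x in C.ravel())
    sum_a = sum(comb(int(x), 2) for x in C.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in C.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return (sum_ij - expected) / (max_idx - expected)


class TestAri:
    def test_identical_labelings_give_one(self, rng):
        lab = rng.integers(0, 4, size=20)
        assert ari(lab, lab.copy()) == pytest.approx(1.0)

    def test_single_cluster_gives_zero(self, rng):
        assert ari(np.zeros(20), rng.integers(0, 3, size=20)) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self, rng):
        a = rng.integers(0, 4, size=30)
        b = rng.integers(0, 3, size=30)
        assert ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_invariant_to_relabeling(self, rng):
        a = rng.integers(0, 4, size=25)
        b = rng.integers(0, 3, size=25)
        assert ari(a, b) == pytest.approx(ari(3 - a, b), abs=1e-12)
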