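"""Pooling-layer primitives against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sanepool.pooling import (EdgeMLPParams, attention_features,
                              attention_scores, edge_attention_mlp,
                              edge_filter, pool_graph, topk_select)


class TestAttentionFeatures:
    def test_single_node_self_loop_identity(self):
        Z = np.array([[0.3, -0.7]])
        H = attention_features(Z, np.zeros((1, 1)), np.eye(2),
                               activation=lambda x: x)
        np.testing.assert_allclose(H, Z)

    def test_row_stochastic_preserves_constant_columns(self, rng):
        A = (rng.random((6, 6)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        Z = np.tile([2.0, -1.0, 0.5], (6, 1))
        H = attention_features(Z, A, np.eye(3), activation=lambda x: x)
        np.testing.assert_allclose(H, Z)

    def test_triangle_matches_dense_oracle(self, rng):
        A = np.ones((3, 3)) - np.eye(3)
        Z = rng.standard_normal((3, 4))
        theta = rng.standard_normal((4, 2))
        # independent dense computation of f(D̃⁻¹ Ã Z Θ)
        A_t = A + np.eye(3)
        D_inv = np.diag(1.0 / A_t.sum(axis=1))
        expected = np.tanh(D_inv @ A_t @ Z @ theta)
        np.testing.assert_allclose(attention_features(Z, A, theta), expected,
                                   atol=1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            attention_features(np.zeros((3, 2)), np.zeros((4, 4)), np.eye(2))


class TestAttentionScores:
    def test_parallel_anti_parallel_orthogonal(self, rng):
        p = rng.standard_normal(6)
        assert attention_scores((2 * p)[None, :], p)[0] == 1.0
        assert attention_scores((-p)[None, :], p)[0] == -1.0
        assert attention_scores(np.array([[0.0, 5.0]]), np.array([1.0, 0.0]))[0] == 0.0

    def test_matches_cosine_oracle(self, rng):
        H = rng.standard_normal((10, 4))
        p = rng.standard_normal(4)
        got = attention_scores(H, p)
        for i in range(10):
            want = H[i] @ p / (np.linalg.norm(H[i]) * np.linalg.norm(p))
            assert got[i] == pytest.approx(want, abs=1e-12)

    def test_zero_row_scores_zero(self):
        H = np.array([[0.0, 0.0], [1.0, 1.0]])
        s = attention_scores(H, np.array([1.0, 0.0]))
        assert s[0] == 0.0

    def test_zero_projection_rejected(self):
        with pytest.raises(ValueError):
            attention_scores(np.ones((2, 2)), np.zeros(2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        H = r.standard_normal((8, 5)) * 10.0 ** r.integers(-8, 8)
        p = r.standard_normal(5) * 10.0 ** r.integers(-8, 8)
        if p @ p == 0:
            return
        s = attention_scores(H, p)
        assert np.all(s >= -1.0) and np.all(s <= 1.0)


class TestTopkSelect:
    def test_exhaustive_sort_oracle(self):
        att = np.array([0.9, 0.1, -0.5])
        np.testing.assert_array_equal(topk_select(att, 2), [0, 1])

    def test_k_equals_n_is_identity(self):
        att = np.array([0.2, -0.1, 0.5])
        np.testing.assert_array_equal(topk_select(att, 3), [0, 1, 2])

    def test_tie_breaks_to_smaller_global_id(self):
        att = np.array([0.5, 0.5])
        np.testing.assert_array_equal(topk_select(att, 1), [0])
        # with reversed global ids the other position wins the tie
        np.testing.assert_array_equal(
            topk_select(att, 1, global_ids=np.array([7, 3])), [1])

    def test_protected_always_kept_and_uncounted(self):
        att = np.array([0.9, 0.1, -0.5, -0.9])
        out = topk_select(att, 2, protected={3})
        np.testing.assert_array_equal(out, [0, 1, 3])

    def test_fractional_k(self):
        att = np.linspace(1, 0, 10)
        assert len(topk_select(att, 0.35)) == 4  # ceil(0.35 * 10)

    def test_random_agrees_with_argsort_oracle(self, rng):
        for _ in range(20):
            att = rng.standard_normal(30)
            k = int(rng.integers(1, 30))
            got = topk_select(att, k)
            want = np.sort(np.argsort(-att, kind="stable")[:k])
            np.testing.assert_array_equal(got, want)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_select(np.ones(3), 0)
        with pytest.raises(ValueError):
            topk_select(np.ones(3), -1.5)

    def test_k_above_gene_count_warns(self):
        with pytest.warns(UserWarning):
            out = topk_select(np.ones(3), 5)
        np.testing.assert_array_equal(out, [0, 1, 2])


class TestPoolGraph:
    def test_all_ones_weighting_is_identity(self, rng):
        A = (rng.random((5, 5)) < 0.5).astype(float)
        A = np.triu(A, 1); A = A + A.T
        idx = np.arange(5)
        A2, _ = pool_graph(A, rng.standard_normal((5, 2)), idx,
                           np.ones((9, 9)), np.arange(5))
        np.testing.assert_array_equal(A2, A)

    def test_hand_hadamard_oracle(self):
        A = np.zeros((4, 4))
        A[0, 2] = A[2, 0] = 1.0
        A[0, 1] = A[1, 0] = 1.0
        W = np.full((6, 6), 0.5)
        W[0, 2] = W[2, 0] = 3.0
        Z = np.arange(8.0).reshape(4, 2)
        A2, Z2 = pool_graph(A, Z, [0, 2], W, np.arange(4))
        np.testing.assert_allclose(A2, [[0.0, 3.0], [3.0, 0.0]])
        np.testing.assert_array_equal(Z2, Z[[0, 2]])

    def test_symmetry_closure_and_no_new_edges(self, rng):
        A = (rng.random((8, 8)) < 0.4).astype(float)
        A = np.triu(A, 1); A = A + A.T
        W = rng.standard_normal((10, 10))
        idx = np.array([1, 3, 4, 6])
        A2, _ = pool_graph(A, rng.standard_normal((8, 3)), idx, W, np.arange(8))
        np.testing.assert_allclose(A2, A2.T)
        assert np.all(A2[A[np.ix_(idx, idx)] == 0] == 0)


class TestEdgeFilter:
    @staticmethod
    def _random_weighted(rng, n=10, p=0.5):
        up = np.triu(rng.standard_normal((n, n)) * (rng.random((n, n)) < p), 1)
        return up + up.T

    def test_keep_all_is_identity(self, rng):
        A = self._random_weighted(rng)
        np.testing.assert_array_equal(edge_filter(A, 1.0), A)

    def test_ninety_percent_of_twenty_keeps_eighteen(self, rng):
        # exactly 20 undirected edges with distinct weights
        n = 10
        iu = np.triu_indices(n, 1)
        pick = rng.choice(iu[0].size, 20, replace=False)
        A = np.zeros((n, n))
        w = rng.permutation(np.arange(1, 21)).astype(float)
        A[iu[0][pick], iu[1][pick]] = w
        A = A + A.T
        out = edge_filter(A, 0.9)
        assert np.count_nonzero(np.triu(out, 1)) == 18

    def test_largest_absolute_weights_survive(self):
        A = np.zeros((5, 5))
        weights = {(0, 1): 5.0, (0, 2): -4.0, (1, 2): 3.0, (2, 3): -2.0, (3, 4): 1.0}
        for (i, j), w in weights.items():
            A[i, j] = A[j, i] = w
        out = edge_filter(A, 0.6)  # ceil(0.6*5) = 3 largest |w|
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(out, 1)))}
        assert kept == {(0, 1), (0, 2), (1, 2)}

    def test_tie_break_lexicographic_pair(self):
        A = np.zeros((4, 4))
        for i, j in [(0, 3), (1, 2), (0, 1)]:
            A[i, j] = A[j, i] = 1.0
        out = edge_filter(A, 0.5)  # keep 2 of 3 equal-weight edges
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(out, 1)))}
        assert kept == {(0, 1), (0, 3)}

    def test_idempotent_under_fixed_budget(self, rng):
        A = self._random_weighted(rng)
        n_edges = np.count_nonzero(np.triu(A, 1))
        once = edge_filter(A, 0.7)
        twice = edge_filter(once, 0.7, total_edges=n_edges)
        np.testing.assert_array_equal(once, twice)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            edge_filter(np.zeros((3, 3)), 0.0)


class TestEdgeAttentionMLP:
    def _params(self, rng, h, m=4):
        return EdgeMLPParams(w1=rng.standard_normal((2 * h, m)),
                             b1=rng.standard_normal(m),
                             w2=rng.standard_normal(m), b2=0.1)

    def test_zero_map_gives_zero_weights(self, rng):
        H = rng.standard_normal((5, 3))
        p = EdgeMLPParams(w1=np.zeros((6, 4)), b1=np.zeros(4),
                          w2=np.zeros(4), b2=0.0)
        np.testing.assert_array_equal(edge_attention_mlp(H, p), np.zeros((5, 5)))

    def test_identical_rows_give_constant_weights(self, rng):
        H = np.tile(rng.standard_normal(3), (6, 1))
        e = edge_attention_mlp(H, self._params(rng, 3))
        assert np.allclose(e, e[0, 0])

    def test_matches_per_pair_oracle(self, rng):
        H = rng.standard_normal((3, 2))
        p = self._params(rng, 2)
        got = edge_attention_mlp(H, p)
        raw = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                cat = np.concatenate([H[i], H[j]])
                hid = np.maximum(cat @ p.w1 + p.b1, 0.0)
                raw[i, j] = max(hid @ p.w2 + p.b2, 0.0)
        np.testing.assert_allclose(got, 0.5 * (raw + raw.T), atol=1e-12)

    def test_node_cap_enforced(self, rng):
        H = rng.standard_normal((20, 2))
        with pytest.raises(ValueError, match="memory"):
            edge_attention_mlp(H, self._params(rng, 2), node_cap=10)
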