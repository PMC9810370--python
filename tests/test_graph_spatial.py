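import numpy as np
import pytest

import graphbold as gb
from graphbold._tensor import Tensor
from graphbold.graph import (DiffusionFilter, GraphConvLayer, WeightedAdjacency,
                             adaptive_adjacency, diffusion_convolution,
                             graph_conv_hybrid, transition_matrix)


def dense_power_series(theta, Td, x):
    """Independent oracle: sum_k theta[k] T^k x with explicit matrix powers."""
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    out = np.zeros((x.shape[0], theta.shape[1]))
    for k in range(theta.shape[0]):
        out += (np.linalg.matrix_power(Td, k) @ x) @ theta[k].T
    return out


class TestTransitionMatrix:
    def test_two_node_symmetric(self):
        A = WeightedAdjacency(np.array([[0.0, 2.0], [2.0, 0.0]]),
                              kind="synthetic")
        T = transition_matrix(A).dense()
        np.testing.assert_allclose(T, [[0, 1], [1, 0]])

    def test_path_middle_row(self, path3):
        T = transition_matrix(path3).dense()
        np.testing.assert_allclose(T[1], [0.5, 0.0, 0.5])

    def test_rows_stochastic(self, small_graph):
        T = transition_matrix(small_graph)
        sums = np.asarray(T.matrix.sum(axis=1)).ravel()
        pos = T.degree > 0
        np.testing.assert_allclose(sums[pos], 1.0, atol=1e-9)
        assert T.matrix.min() >= 0

    def test_invariant_to_global_weight_scale(self, small_graph):
        T1 = transition_matrix(small_graph).dense()
        T2 = transition_matrix(
            WeightedAdjacency(small_graph.weights * 17.3, kind="synthetic")
        ).dense()
        np.testing.assert_allclose(T1, T2, atol=1e-12)

    def test_zero_degree_row_is_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0  # node 2 isolated
        T = transition_matrix(WeightedAdjacency(w, kind="synthetic"))
        np.testing.assert_array_equal(T.dense()[2], 0.0)

    def test_negative_similarity_clipped(self):
        w = np.array([[0.0, -0.5, 0.8], [-0.5, 0.0, 0.2], [0.8, 0.2, 0.0]])
        T = transition_matrix(WeightedAdjacency(w, kind="CE")).dense()
        assert T.min() >= 0
        assert T[0, 1] == 0.0  # negative edge removed


class TestDiffusionConvolution:
    def test_identity_case(self, rng):
        """K=0, theta_0 = 1 reproduces the input exactly."""
        T = transition_matrix(gb.make_graph(6, 0.5, seed=1))
        x = rng.normal(size=6)
        y = diffusion_convolution(x, T, DiffusionFilter(np.ones((1, 1, 1))))
        np.testing.assert_allclose(y, x)

    def test_path_one_hop(self, path3):
        T = transition_matrix(path3)
        filt = DiffusionFilter(np.array([0.0, 1.0]).reshape(2, 1, 1))
        y = diffusion_convolution(np.array([1.0, 0.0, 0.0]), T, filt)
        np.testing.assert_allclose(y, [0.0, 0.5, 0.0])

    def test_matches_dense_oracle(self, rng):
        T = transition_matrix(gb.make_graph(10, 0.3, seed=3))
        theta = rng.normal(size=(4, 3, 2))
        x = rng.normal(size=(10, 2))
        y = diffusion_convolution(x, T, DiffusionFilter(theta))
        np.testing.assert_allclose(y, dense_power_series(theta, T.dense(), x),
                                   atol=1e-10)

    def test_component_locality(self):
        """Signals never cross between disconnected components."""
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            w[i, j] = w[j, i] = 1.0
        T = transition_matrix(WeightedAdjacency(w, kind="synthetic"))
        filt = DiffusionFilter(np.random.default_rng(0).normal(size=(5, 1, 1)))
        x = np.zeros(6)
        x[0] = 1.0
        y = diffusion_convolution(x, T, filt)
        np.testing.assert_array_equal(y[3:], 0.0)


class TestAdaptiveAdjacency:
    def test_zero_matrix(self):
        np.testing.assert_array_equal(adaptive_adjacency(np.zeros((5, 5))), 0.0)

    def test_closed_form_entry(self):
        V = np.zeros((4, 4))
        V[1, 2] = 1.0
        A = adaptive_adjacency(V)
        assert A[1, 2] == pytest.approx(np.tanh(1.0) / 4, abs=1e-12)
        assert A[1, 2] == pytest.approx(0.190399, abs=1e-6)

    def test_entries_strictly_bounded(self, rng):
        V = rng.uniform(-8, 8, size=(7, 7))
        A = adaptive_adjacency(V)
        assert np.all(np.abs(A) < 1.0 / 7)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            adaptive_adjacency(np.zeros((3, 4)))


class TestHybridConvolution:
    def test_reduces_to_diffusion_without_adaptive(self, rng, small_graph):
        T = transition_matrix(small_graph)
        theta = rng.normal(size=(3, 2, 1))
        x = rng.normal(size=(10, 1))
        filt = DiffusionFilter(theta)
        y = graph_conv_hybrid(x, T, None, filt=filt)
        np.testing.assert_allclose(y, diffusion_convolution(x, T, filt))

    def test_zero_coefficients_zero_output(self, rng, small_graph):
        T = transition_matrix(small_graph)
        x = rng.normal(size=(10, 1))
        y = graph_conv_hybrid(x, T, adaptive_adjacency(rng.normal(size=(10, 10))),
                              filt=DiffusionFilter(np.zeros((3, 2, 1))),
                              filt_adap=DiffusionFilter(np.zeros((3, 2, 1))))
        np.testing.assert_array_equal(y, 0.0)

    def test_matches_double_power_series_oracle(self, rng):
        N, K = 8, 2
        T = transition_matrix(gb.make_graph(N, 0.4, seed=9))
        A = adaptive_adjacency(rng.normal(size=(N, N)))
        th = rng.normal(size=(K + 1, 2, 1))
        th_a = rng.normal(size=(K + 1, 2, 1))
        x = rng.normal(size=(N, 1))
        y = graph_conv_hybrid(x, T, A, DiffusionFilter(th),
                              DiffusionFilter(th_a))
        oracle = dense_power_series(th, T.dense(), x) + \
            dense_power_series(th_a, A, x)
        np.testing.assert_allclose(y, oracle, atol=1e-10)

    def test_both_operators_absent_rejected(self, rng):
        with pytest.raises(ValueError):
            graph_conv_hybrid(rng.normal(size=(4, 1)), None, None)


class TestGraphConvLayer:
    def test_matches_functional_path(self, rng, small_graph):
        """The trainable autodiff layer computes the same power series as
        the functional implementation for shared coefficients (K-branch
        bookkeeping cross-check)."""
        T = transition_matrix(small_graph)
        layer = GraphConvLayer(2, 3, K=2, supports=[T.matrix], adaptive=None,
                               rng=rng)
        x = rng.normal(size=(4, 10, 2))
        out = layer(Tensor(x)).data
        theta = np.transpose(layer.theta.data, (0, 2, 1))  # (K+1, Q, M)
        for b in range(4):
            oracle = dense_power_series(theta, T.dense(), x[b]) + layer.bias.data
            np.testing.assert_allclose(out[b], oracle, atol=1e-10)

    def test_gradients_match_finite_differences(self, rng, small_graph):
        T = transition_matrix(small_graph)
        layer = GraphConvLayer(1, 2, K=1, supports=[T.matrix], adaptive=None,
                               rng=rng)
        x = rng.normal(size=(2, 10, 1))
        loss = (layer(Tensor(x)) ** 2.0).mean()
        loss.backward()
        g = layer.theta.grad.copy()
        eps = 1e-6
        idx = (1, 0, 1)
        orig = layer.theta.data[idx]
        layer.theta.data[idx] = orig + eps
        l_up = float((layer(Tensor(x)) ** 2.0).mean().data)
        layer.theta.data[idx] = orig - eps
        l_dn = float((layer(Tensor(x)) ** 2.0).mean().data)
        layer.theta.data[idx] = orig
        assert g[idx] == pytest.approx((l_up - l_dn) / (2 * eps), abs=1e-7)
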