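"""Learnable adjacency, symmetric normalization, Chebyshev bank, graph conv."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegdann import autodiff as ad
from eegdann.autodiff import Tensor
from eegdann.exceptions import ConfigurationError
from eegdann.graph import (AdjacencyState, ChebGraphExtractor, GraphConvLayer,
                           MLPExtractor, chebyshev_stack, graph_conv_forward,
                           init_adjacency, normalize_adjacency)
from eegdann.nn import RMSprop


class TestInitAdjacency:
    def test_62_channel_init_is_symmetric_and_bounded(self):
        state = init_adjacency(62, seed=0)
        a = state.raw_weights
        assert a.shape == (62, 62)
        np.testing.assert_array_equal(a, a.T)
        bound = 1.0 / np.sqrt(62)
        assert np.all(np.abs(a) < bound)

    def test_same_seed_reproduces(self):
        a = init_adjacency(10, seed=5).raw_weights
        b = init_adjacency(10, seed=5).raw_weights
        np.testing.assert_array_equal(a, b)

    def test_entries_have_zero_mean_uniform_law(self):
        # pool many draws; mean of U(-b, b) is 0 with se = b/sqrt(3 n)
        draws = np.concatenate([
            init_adjacency(4, seed=s).raw_weights.ravel() for s in range(6250)
        ])
        b = 1.0 / np.sqrt(4)
        se = b / np.sqrt(3 * draws.size)
        assert abs(draws.mean()) < 3 * se

    def test_too_few_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            init_adjacency(1, seed=0)


class TestNormalizeAdjacency:
    def test_all_ones_two_by_two(self):
        state = normalize_adjacency(np.ones((2, 2)))
        np.testing.assert_allclose(state.normalized, np.full((2, 2), 0.5))
        np.testing.assert_allclose(state.degree, [2.0, 2.0])

    def test_all_negative_row_becomes_zero_row_without_blowup(self):
        a = np.array([[1.0, -2.0, 0.5],
                      [-2.0, -1.0, -3.0],
                      [0.5, -3.0, 2.0]])
        state = normalize_adjacency(a)
        assert np.all(np.isfinite(state.normalized))
        np.testing.assert_array_equal(state.normalized[1, :], 0.0)
        np.testing.assert_array_equal(state.normalized[:, 1], 0.0)

    def test_positive_diagonal_normalizes_to_identity(self):
        state = normalize_adjacency(np.diag([2.0, 5.0, 0.25]))
        np.testing.assert_allclose(state.normalized, np.eye(3), atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.ones((2, 3)))

    def test_symmetry_and_spectral_radius_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 12)
            a = rng.normal(size=(n, n))
            L = normalize_adjacency(a).normalized
            np.testing.assert_allclose(L, L.T, atol=1e-12)
            eig = np.linalg.eigvalsh(L)
            assert eig.max() <= 1 + 1e-6 and eig.min() >= -1 - 1e-6


class TestChebyshevStack:
    def test_order_one_is_identity(self):
        bank = chebyshev_stack(np.eye(4) * 0.3, order=1)
        np.testing.assert_array_equal(bank.polynomials[0], np.eye(4))

    def test_diagonal_operator_matches_scalar_t2(self):
        lam = np.array([0.1, -0.5, 0.9])
        bank = chebyshev_stack(np.diag(lam), order=3)
        np.testing.assert_allclose(np.diag(bank.polynomials[2]),
                                   2 * lam ** 2 - 1, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(5, 10), k=st.integers(1, 8),
           seed=st.integers(0, 10_000))
    def test_matches_eigendecomposition_oracle(self, n, k, seed):
        """T_k(L) must equal U T_k(Lambda) U^T computed per eigenvalue."""
        rng = np.random.default_rng(seed)
        L = normalize_adjacency(rng.normal(size=(n, n))).normalized
        lam, U = np.linalg.eigh(L)
        bank = chebyshev_stack(L, order=k)
        t_prev, t_cur = np.ones_like(lam), lam.copy()
        for j in range(k):
            if j == 0:
                scalar = np.ones_like(lam)
            elif j == 1:
                scalar = lam
            else:
                t_prev, t_cur = t_cur, 2 * lam * t_cur - t_prev
                scalar = t_cur
            oracle = (U * scalar) @ U.T
            np.testing.assert_allclose(bank.polynomials[j], oracle, atol=1e-6)

    def test_order_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            chebyshev_stack(np.eye(3), order=0)


class TestGraphConvForward:
    def test_identity_filter_passes_nonnegative_input_through(self):
        x = np.abs(np.random.default_rng(0).normal(size=(2, 4, 3)))
        bank = chebyshev_stack(np.zeros((4, 4)), order=1)
        layer = GraphConvLayer(weights=[np.eye(3)])
        np.testing.assert_allclose(graph_conv_forward(x, bank, layer), x)

    def test_matches_hand_computed_two_term_sum(self):
        # 3 channels, 2 input features, 2 output features, K = 2
        L = normalize_adjacency(np.ones((3, 3))).normalized
        x = np.array([[[1.0, 2.0], [0.0, -1.0], [3.0, 0.5]]])
        w0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        w1 = np.array([[0.5, -0.5], [1.0, 0.0]])
        expected = x[0] @ w0 + (L @ x[0]) @ w1   # T0 = I, T1 = L
        expected = np.where(expected >= 0, expected, 0.01 * expected)
        bank = chebyshev_stack(L, order=2)
        out = graph_conv_forward(x, bank, GraphConvLayer(weights=[w0, w1]))
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        bank = chebyshev_stack(np.eye(3), order=1)
        layer = GraphConvLayer(weights=[np.eye(4)])
        with pytest.raises(ValueError):
            graph_conv_forward(np.zeros((1, 3, 3)), bank, layer)


class TestChebGraphExtractor:
    def _extractor(self, seed=0, **kw):
        rng = np.random.default_rng(seed)
        kw.setdefault("order", 3)
        kw.setdefault("out_dim", 4)
        return ChebGraphExtractor(5, 3, rng, **kw)

    def test_output_shape_and_row_purity(self):
        ext = self._extractor()
        x = np.random.default_rng(1).normal(size=(6, 5, 3))
        x[3] = x[0]
        out = ext(Tensor(x)).data
        assert out.shape == (6, 5 * 4)
        np.testing.assert_array_equal(out[3], out[0])

    def test_adjacency_gradient_matches_finite_differences(self):
        ext = self._extractor()
        x = Tensor(np.random.default_rng(2).normal(size=(2, 5, 3)))

        def loss_at(raw):
            ext.adjacency.data = raw
            return ext(x).sum().item()

        base = ext.adjacency.data.copy()
        ext(x).sum().backward()
        autodiff_grad = ext.adjacency.grad.copy()
        eps = 1e-6
        for idx in [(0, 1), (2, 2), (4, 0)]:
            up, dn = base.copy(), base.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (loss_at(up) - loss_at(dn)) / (2 * eps)
            ext.adjacency.data = base
            assert autodiff_grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_permutation_equivariance_before_flatten(self):
        ext = self._extractor()
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 5, 3))
        perm = rng.permutation(5)
        out = ext.pre_flatten(Tensor(x)).data
        ext.adjacency.data = ext.adjacency.data[np.ix_(perm, perm)]
        out_p = ext.pre_flatten(Tensor(x[:, perm, :])).data
        np.testing.assert_allclose(out_p, out[:, perm, :], atol=1e-10)

    def test_symmetrized_adjacency_stays_symmetric_after_optimizer_step(self):
        ext = self._extractor()
        opt = RMSprop(ext.parameters, lr=1e-2)
        x = Tensor(np.random.default_rng(4).normal(size=(3, 5, 3)))
        for _ in range(3):
            (ext(x) ** 2.0).sum().backward()
            opt.step()
            opt.zero_grad()
            a = ext.learned_adjacency()
            np.testing.assert_array_equal(a, a.T)

    def test_mlp_ablation_matches_output_dimensionality(self):
        rng = np.random.default_rng(0)
        mlp = MLPExtractor(5, 3, rng, out_dim=4)
        cheb = self._extractor()
        x = Tensor(np.random.default_rng(1).normal(size=(2, 5, 3)))
        assert mlp(x).shape == cheb(x).shape == (2, 20)
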