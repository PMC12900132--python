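"""Closed forms, brute-force oracles and invariances of the loss terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegdann.autodiff import Tensor
from eegdann.exceptions import ConfigurationError
from eegdann.objectives import (CLAMP_EPS, bce, classification_loss,
                                cluster_loss, domain_loss, individual_loss,
                                select_confident_targets, total_loss)


def loop_bce(y, p):
    p = np.clip(p, CLAMP_EPS, 1 - CLAMP_EPS)
    total = 0.0
    for yi, pi in zip(np.ravel(y), np.ravel(p)):
        total += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
    return total / np.size(y)


class TestBce:
    def test_perfect_prediction_is_near_zero(self):
        assert bce(np.array([1., 0., 1.]), np.array([1., 0., 1.])).item() == \
            pytest.approx(0.0, abs=1e-5)

    def test_half_probability_is_ln2(self):
        assert bce(np.ones(4), np.full(4, 0.5)).item() == pytest.approx(np.log(2))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_matches_elementwise_loop_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n).astype(float)
        p = rng.uniform(0.001, 0.999, size=n)
        assert bce(y, p).item() == pytest.approx(loop_bce(y, p), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce(np.ones(3), np.ones(4) * 0.5)


class TestDomainLoss:
    def test_perfect_discrimination_near_zero(self):
        assert domain_loss(np.full(5, 1 - 1e-9), np.full(5, 1e-9)).item() == \
            pytest.approx(0.0, abs=1e-5)

    def test_all_half_equals_ln2(self):
        assert domain_loss(np.full(3, 0.5), np.full(7, 0.5)).item() == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_matches_two_term_hand_formula(self):
        rng = np.random.default_rng(0)
        ds = rng.uniform(0.01, 0.99, size=8)
        dt = rng.uniform(0.01, 0.99, size=5)
        expected = 0.5 * (loop_bce(np.ones(8), ds) + loop_bce(np.zeros(5), dt))
        assert domain_loss(ds, dt).item() == pytest.approx(expected, abs=1e-10)

    def test_symmetric_under_label_and_probability_swap(self):
        rng = np.random.default_rng(1)
        ds = rng.uniform(0.05, 0.95, size=6)
        dt = rng.uniform(0.05, 0.95, size=6)
        assert domain_loss(ds, dt).item() == \
            pytest.approx(domain_loss(1 - dt, 1 - ds).item(), abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ConfigurationError):
            domain_loss(np.ones(0), np.full(3, 0.5))


class TestIndividualLoss:
    def test_one_hot_correct_near_zero(self):
        p = np.eye(4)[[0, 2, 3]]
        assert individual_loss(p, [0, 2, 3], 4).item() == pytest.approx(0.0, abs=1e-5)

    def test_uniform_fifteen_subjects_is_ln15(self):
        p = np.full((6, 15), 1 / 15)
        assert individual_loss(p, np.arange(6), 15).item() == \
            pytest.approx(np.log(15), abs=1e-12)

    def test_matches_per_row_loop_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 1, size=(10, 5))
        p /= p.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 5, size=10)
        expected = np.mean([-np.log(np.clip(p[i, labels[i]], CLAMP_EPS, None))
                            for i in range(10)])
        assert individual_loss(p, labels, 5).item() == pytest.approx(expected, abs=1e-10)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            individual_loss(np.full((2, 3), 1 / 3), [0, 3], 3)


class TestClassificationLoss:
    def test_perfect_one_hot_scores_near_zero(self):
        scores = np.eye(3)[[1, 0, 2]] * (1 - 2e-7) + 1e-7
        assert classification_loss(scores, [1, 0, 2], 3).item() == \
            pytest.approx(0.0, abs=1e-5)

    def test_all_half_scores_give_ln2_for_any_labels(self):
        scores = np.full((5, 3), 0.5)
        assert classification_loss(scores, [0, 1, 2, 0, 1], 3).item() == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_one_vs_all_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.01, 0.99, size=(8, 4))
        labels = rng.integers(0, 4, size=8)
        onehot = np.eye(4)[labels]
        assert classification_loss(scores, labels, 4).item() == \
            pytest.approx(loop_bce(onehot, scores), abs=1e-10)

    def test_softmax_head_is_mean_negative_log_probability(self):
        p = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        expected = -(np.log(0.7) + np.log(0.8)) / 2
        assert classification_loss(p, [0, 1], 3, head="softmax_ce").item() == \
            pytest.approx(expected, abs=1e-10)

    def test_unknown_head_rejected(self):
        with pytest.raises(ConfigurationError):
            classification_loss(np.full((1, 2), 0.5), [0], 2, head="hinge")


class TestSelectConfidentTargets:
    def test_all_above_threshold_selected(self):
        scores = np.full((4, 3), 0.02)
        scores[:, 0] = 0.95
        idx, n = select_confident_targets(scores, threshold=0.9)
        assert n == 4 and list(idx) == [0, 1, 2, 3]

    def test_none_selected_gives_empty_set_and_zero_cluster_loss(self):
        scores = np.full((4, 3), 0.5)
        idx, n = select_confident_targets(scores, threshold=0.9)
        assert n == 0 and idx.size == 0
        assert cluster_loss(np.ones(0)).item() == 0.0

    def test_top_fraction_takes_exactly_the_largest_half(self):
        conf = np.linspace(0.1, 0.95, 10)
        scores = np.zeros((10, 2))
        scores[:, 0] = conf
        idx, n = select_confident_targets(scores, rule="top_fraction",
                                          fraction=0.5)
        assert n == 5
        assert sorted(idx) == [5, 6, 7, 8, 9]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            select_confident_targets(np.ones((2, 2)), rule="similarity")


class TestClusterLoss:
    def test_source_like_targets_near_zero(self):
        assert cluster_loss(np.full(5, 1 - 1e-9)).item() == pytest.approx(0.0, abs=1e-5)

    def test_single_half_row_is_ln2(self):
        assert cluster_loss(np.array([0.5])).item() == pytest.approx(np.log(2))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0.05, 0.95, size=7)
        assert cluster_loss(d).item() == pytest.approx(loop_bce(np.ones(7), d), abs=1e-10)

    def test_monotone_decreasing_as_probabilities_approach_one(self):
        vals = [cluster_loss(np.full(4, p)).item() for p in (0.2, 0.5, 0.8, 0.99)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestTotalLoss:
    def test_weighted_sum_arithmetic(self):
        b = total_loss(Tensor(1.0), Tensor(2.0), Tensor(3.0), Tensor(4.0),
                       lambda_cluster=0.5, n_selected=2)
        assert b.total.item() == pytest.approx(8.0)

    def test_lambda_zero_ignores_cluster_term(self):
        b1 = total_loss(Tensor(1.0), Tensor(1.0), Tensor(1.0), Tensor(9.0), 0.0)
        b2 = total_loss(Tensor(1.0), Tensor(1.0), Tensor(1.0), Tensor(0.0), 0.0)
        assert b1.total.item() == b2.total.item() == 3.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_total_equals_recomputed_sum(self, seed):
        rng = np.random.default_rng(seed)
        c, d, i, k = rng.uniform(0, 3, size=4)
        lam = rng.uniform(0, 2)
        b = total_loss(Tensor(c), Tensor(d), Tensor(i), Tensor(k), lam)
        assert b.total.item() == pytest.approx(c + d + i + lam * k, abs=1e-12)


class TestPermutationInvariance:
    def test_losses_invariant_to_row_permutation(self):
        rng = np.random.default_rng(5)
        perm = rng.permutation(8)
        ds = rng.uniform(0.05, 0.95, size=8)
        dt = rng.uniform(0.05, 0.95, size=8)
        assert domain_loss(ds, dt).item() == \
            pytest.approx(domain_loss(ds[perm], dt[perm]).item(), abs=1e-12)
        p = rng.uniform(0.01, 1, size=(8, 4))
        p /= p.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 4, size=8)
        assert individual_loss(p, labels, 4).item() == \
            pytest.approx(individual_loss(p[perm], labels[perm], 4).item(), abs=1e-12)
        scores = rng.uniform(0.01, 0.99, size=(8, 3))
        y = rng.integers(0, 3, size=8)
        assert classification_loss(scores, y, 3).item() == \
            pytest.approx(classification_loss(scores[perm], y[perm], 3).item(),
                          abs=1e-12)
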