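"""Loss functions and the shared-neighbor pseudo-label estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgcn import (
    LossWeights,
    PairwiseLabels,
    estimate_pairwise_labels,
    graph_center_loss,
    pseudo_contrastive_loss,
    total_loss,
    transform_invariant_loss,
)
from dgcn.exceptions import ConfigurationError, InvalidInputError, NumericError
from dgcn.objectives import (
    graph_center_loss_grad,
    pseudo_contrastive_loss_grad,
    transform_invariant_loss_grad,
)


def _labels(mat):
    return PairwiseLabels(l=np.asarray(mat, dtype=np.int8), lam=1)


class TestGraphCenterLoss:
    def test_identical_rows_zero(self):
        Z = np.ones((4, 3))
        A = 1 - np.eye(4)
        assert graph_center_loss(Z, A) == 0.0

    def test_hand_value_two_nodes(self):
        Z = np.array([[0.0, 0.0], [3.0, 4.0]])
        A = np.array([[0, 1], [1, 0]])
        assert graph_center_loss(Z, A) == pytest.approx(25.0)

    def test_empty_graph_zero(self):
        Z = np.arange(6.0).reshape(3, 2)
        assert graph_center_loss(Z, np.zeros((3, 3))) == 0.0

    def test_misaligned_rejected(self):
        with pytest.raises(InvalidInputError):
            graph_center_loss(np.zeros((3, 2)), np.zeros((4, 4)))

    def test_translation_invariance(self, rng):
        Z = rng.normal(size=(6, 4))
        A = (1 - np.eye(6)) * rng.integers(0, 2, size=(6, 6))
        A = np.maximum(A, A.T)
        shifted = Z + rng.normal(size=(1, 4))
        assert graph_center_loss(shifted, A) == pytest.approx(
            graph_center_loss(Z, A), rel=1e-10
        )


class TestPairwiseLabelEstimator:
    def test_full_overlap_above_threshold(self):
        lab = estimate_pairwise_labels([np.array([1, 2, 3])] * 2, lam=2)
        assert lab.l[0, 1] == 1

    def test_no_overlap_is_zero_even_at_lambda_zero(self):
        lab = estimate_pairwise_labels([np.array([1, 2, 3]), np.array([4, 5, 6])], lam=0)
        assert lab.l[0, 1] == 0

    def test_strict_inequality_at_threshold(self):
        sets = [np.array([1, 2, 3]), np.array([2, 3, 4])]
        assert estimate_pairwise_labels(sets, lam=1).l[0, 1] == 1
        assert estimate_pairwise_labels(sets, lam=2).l[0, 1] == 0

    def test_lambda_above_k_warns_and_zeroes(self):
        sets = [np.array([1, 2]), np.array([1, 2])]
        with pytest.warns(UserWarning):
            lab = estimate_pairwise_labels(sets, lam=3)
        assert lab.l.sum() == 0

    def test_symmetry(self, rng):
        sets = [rng.choice(12, size=4, replace=False) for _ in range(8)]
        lab = estimate_pairwise_labels(sets, lam=1)
        assert np.array_equal(lab.l, lab.l.T)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_shared_neighbors(self, seed):
        # adding one element to both neighbor sets never flips 1 -> 0
        rng = np.random.default_rng(seed)
        a = rng.choice(20, size=4, replace=False)
        b = rng.choice(20, size=4, replace=False)
        lam = int(rng.integers(0, 4))
        extra = 30
        before = estimate_pairwise_labels([a, b], lam).l[0, 1]
        after = estimate_pairwise_labels(
            [np.append(a, extra), np.append(b, extra)], lam
        ).l[0, 1]
        assert after >= before


class TestPseudoContrastiveLoss:
    def test_same_class_zero_distance(self):
        Z = np.zeros((2, 3))
        assert pseudo_contrastive_loss(Z, _labels([[0, 1], [1, 0]]), margin=2.0) == 0.0

    def test_far_negative_pair_zero(self):
        Z = np.array([[0.0], [3.0]])
        assert pseudo_contrastive_loss(Z, _labels([[0, 0], [0, 0]]), margin=2.0) == 0.0

    def test_hand_values(self):
        Z = np.array([[0.0], [1.0]])
        assert pseudo_contrastive_loss(Z, _labels([[0, 0], [0, 0]]), 2.0) == pytest.approx(0.5)
        Z = np.array([[0.0], [2.0]])
        assert pseudo_contrastive_loss(Z, _labels([[0, 1], [1, 0]]), 2.0) == pytest.approx(2.0)

    def test_margin_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            pseudo_contrastive_loss(np.zeros((2, 1)), _labels([[0, 1], [1, 0]]), 0.0)

    def test_permutation_invariance(self, rng):
        Z = rng.normal(size=(6, 3))
        lmat = rng.integers(0, 2, size=(6, 6))
        lmat = np.maximum(lmat, lmat.T)
        np.fill_diagonal(lmat, 0)
        perm = rng.permutation(6)
        a = pseudo_contrastive_loss(Z, _labels(lmat), 1.0)
        b = pseudo_contrastive_loss(Z[perm], _labels(lmat[np.ix_(perm, perm)]), 1.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestTransformInvariantLoss:
    def test_identity_zero(self, rng):
        Z = rng.normal(size=(5, 4))
        assert transform_invariant_loss(Z, Z.copy()) == 0.0

    def test_mean_of_row_norms(self):
        Z = np.zeros((2, 2))
        Zt = np.array([[3.0, 0.0], [0.0, 1.0]])
        assert transform_invariant_loss(Z, Zt) == pytest.approx(2.0)

    def test_single_row(self):
        assert transform_invariant_loss(
            np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        ) == pytest.approx(5.0)

    def test_squared_variant(self):
        Z = np.zeros((2, 1))
        Zt = np.array([[2.0], [4.0]])
        assert transform_invariant_loss(Z, Zt, squared=True) == pytest.approx(10.0)

    def test_row_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            transform_invariant_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_joint_translation_invariance(self, rng):
        Z, Zt = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        shift = rng.normal(size=(1, 3))
        assert transform_invariant_loss(Z + shift, Zt + shift) == pytest.approx(
            transform_invariant_loss(Z, Zt), rel=1e-12
        )


class TestTotalLoss:
    def test_weighted_combination(self):
        rep = total_loss(0.5, 25.0, 2.0, LossWeights(alpha=1.0, beta=1.0))
        assert rep.total == pytest.approx(27.5)

    def test_zero_weights_reduce_to_pc(self):
        rep = total_loss(0.7, 9.0, 4.0, LossWeights(alpha=0.0, beta=0.0))
        assert rep.total == pytest.approx(0.7)

    def test_all_zero(self):
        assert total_loss(0, 0, 0, LossWeights()).total == 0.0

    def test_non_finite_component_rejected(self):
        with pytest.raises(NumericError):
            total_loss(np.nan, 0.0, 0.0, LossWeights())


class TestAnalyticGradients:
    """Loss gradients w.r.t. Z match central differences (independent check
    of the formulas used by the trainer's backward pass)."""

    @staticmethod
    def _fd_grad(fn, Z, h=1e-7):
        g = np.zeros_like(Z)
        for idx in np.ndindex(Z.shape):
            Zp, Zm = Z.copy(), Z.copy()
            Zp[idx] += h
            Zm[idx] -= h
            g[idx] = (fn(Zp) - fn(Zm)) / (2 * h)
        return g

    def test_graph_center_grad(self, rng):
        Z = rng.normal(size=(5, 3))
        A = np.maximum(*(2 * [rng.integers(0, 2, size=(5, 5))])).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        fd = self._fd_grad(lambda z: graph_center_loss(z, A), Z)
        assert np.allclose(graph_center_loss_grad(Z, A), fd, atol=1e-6)

    def test_pseudo_contrastive_grad(self, rng):
        Z = rng.normal(size=(6, 3))
        lmat = rng.integers(0, 2, size=(6, 6))
        lmat = np.maximum(lmat, lmat.T)
        np.fill_diagonal(lmat, 0)
        lab = _labels(lmat)
        fd = self._fd_grad(lambda z: pseudo_contrastive_loss(z, lab, 1.5), Z)
        assert np.allclose(pseudo_contrastive_loss_grad(Z, lab, 1.5), fd, atol=1e-6)

    def test_transform_invariant_grad(self, rng):
        Z, Zt = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        gz, gzt = transform_invariant_loss_grad(Z, Zt)
        fd_z = self._fd_grad(lambda z: transform_invariant_loss(z, Zt), Z)
        fd_zt = self._fd_grad(lambda z: transform_invariant_loss(Z, z), Zt)
        assert np.allclose(gz, fd_z, atol=1e-6)
        assert np.allclose(gzt, fd_zt, atol=1e-6)
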