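"""Retention mechanism: recurrence, parallel duality, decay, GroupNorm."""

import numpy as np
import pytest

from pkaret import retention as ret
from pkaret.autodiff import Tensor
from pkaret.chem_graph import InterAtomicMatrices, interatomic_matrices, parse_molecule


class TestRecurrentRetention:
    def test_hand_evaluated_scalar_recurrence(self):
        """q=k=v=1 at every step, gamma=0.5: S_1=1 -> out 1; S_2=1.5 -> out 1.5."""
        ones = np.ones((2, 1))
        out, S = ret.recurrent_retention(ones, ones, ones, gamma=0.5)
        assert np.allclose(out, [[1.0], [1.5]])
        assert np.allclose(S, [[1.5]])

    def test_gamma_zero_collapses_to_local_bilinear(self, rng):
        Q, K, V = (rng.normal(size=(5, 3)) for _ in range(3))
        out, _ = ret.recurrent_retention(Q, K, V, gamma=0.0)
        local = np.array([np.outer(K[n], V[n]).T @ Q[n] for n in range(5)])
        assert np.allclose(out, local)

    def test_zero_values_give_zero_outputs(self, rng):
        Q = rng.normal(size=(4, 2))
        out, S = ret.recurrent_retention(Q, Q, np.zeros((4, 2)), gamma=0.9)
        assert np.all(out == 0) and np.all(S == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ret.recurrent_retention(np.ones((2, 1)), np.ones((3, 1)),
                                    np.ones((3, 1)), 0.5)


class TestParallelRetention:
    def test_equals_recurrent_on_random_instances(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 33))
            dk, dv = int(rng.integers(1, 17)), int(rng.integers(1, 17))
            Q, K = rng.normal(size=(L, dk)), rng.normal(size=(L, dk))
            V = rng.normal(size=(L, dv))
            gamma = float(rng.uniform(0.01, 0.99))
            rec, _ = ret.recurrent_retention(Q, K, V, gamma)
            par = ret.parallel_retention(Q, K, V, ret.sequence_decay_matrix(L, gamma))
            assert np.abs(rec - par).max() < 1e-5

    def test_single_position(self, rng):
        Q, K, V = (rng.normal(size=(1, 3)) for _ in range(3))
        out = ret.parallel_retention(Q, K, V, np.ones((1, 1)))
        assert np.allclose(out, (Q @ K.T) @ V)

    def test_identity_decay_masks_history(self, rng):
        Q, K, V = (rng.normal(size=(6, 4)) for _ in range(3))
        out = ret.parallel_retention(Q, K, V, np.eye(6))
        local = np.array([(Q[n] @ K[n]) * V[n] for n in range(6)])
        assert np.allclose(out, local)


class TestGraphDecay:
    def test_power_evaluation(self):
        D = ret.graph_decay_matrix(np.array([[0.0, 2], [2, 0]]), gamma=0.5)
        assert np.allclose(D, [[1.0, 0.25], [0.25, 1.0]])

    def test_disconnected_sentinel_is_near_zero(self):
        Dtop = np.full((10, 10), 10.0)
        np.fill_diagonal(Dtop, 0.0)
        D = ret.graph_decay_matrix(Dtop, gamma=0.5)
        assert D[0, 1] == pytest.approx(0.5 ** 10)
        assert np.all(np.diag(D) == 1.0)

    @pytest.mark.parametrize("gamma", [0.0, 1.0, -0.2, 1.5])
    def test_gamma_domain_enforced(self, gamma):
        with pytest.raises(ValueError, match="gamma"):
            ret.graph_decay_matrix(np.zeros((2, 2)), gamma)

    def test_monotone_decay_of_contributions(self):
        """With non-negative scores, a neighbor's contribution never grows
        with its topological distance."""
        distances = np.arange(1, 8, dtype=float)
        weights = [0.7 ** d for d in distances]
        assert all(a >= b for a, b in zip(weights, weights[1:]))
        # full operator check: one query atom, neighbors at growing distance
        n = 8
        Dtop = np.zeros((n, n))
        Dtop[0, 1:] = Dtop[1:, 0] = distances
        Q = np.ones((n, 1))
        K = np.ones((n, 1))
        V = np.eye(n)[:, :1] * 0 + 1.0
        D = ret.graph_decay_matrix(Dtop, 0.7)
        contrib = (Q @ K.T * D)[0, 1:]
        assert np.all(np.diff(contrib) <= 1e-12)


class TestGroupNorm:
    def test_two_value_group(self):
        out = ret.group_normalize(np.array([[1.0, 3.0]]), 1, eps=1e-12)
        assert np.allclose(out, [[-1.0, 1.0]], atol=1e-5)

    @pytest.mark.parametrize("c", [0.1, 10.0, 1e3])
    def test_positive_scale_invariance(self, c, rng):
        # invariance holds exactly in the eps -> 0 limit; use a negligible eps
        X = rng.normal(size=(5, 12))
        assert np.abs(ret.group_normalize(c * X, 4, eps=1e-12)
                      - ret.group_normalize(X, 4, eps=1e-12)).max() < 1e-5

    def test_constant_group_is_finite_and_near_zero(self):
        out = ret.group_normalize(np.full((2, 4), 3.0), 2)
        assert np.all(np.isfinite(out)) and np.abs(out).max() < 1e-3

    def test_indivisible_grouping_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ret.group_normalize(np.zeros((2, 5)), 2)


class TestRetentionParams:
    def test_gamma_schedule_in_unit_interval(self):
        g = ret.gamma_schedule(8)
        assert np.all((g > 0) & (g < 1)) and np.all(np.diff(g) > 0)

    def test_bias_requires_heads_divisible_by_three(self, rng):
        with pytest.raises(ValueError, match="divisible by 3"):
            ret.RetentionParams.create(8, 4, rng, use_bias=True)

    def test_unknown_bias_matrix_rejected(self, rng):
        p = ret.RetentionParams.create(6, 3, rng, use_bias=False)
        with pytest.raises(ValueError, match="unknown"):
            ret.RetentionParams(n_heads=3, head_dim=2, gammas=p.gammas,
                                Wq=p.Wq, Wk=p.Wk, Wv=p.Wv, Wo=p.Wo,
                                bias_assignment=("adjacency", "nope", "none"),
                                n_groups=3)


def _zero_bias_mats(n):
    Z = np.zeros((n, n))
    return InterAtomicMatrices(A=Z, Dtop=Z, C=Z, A_scaled=Z, Dtop_scaled=Z,
                               C_scaled=Z)


class TestBiasedMultiheadRetention:
    def test_zero_bias_matrices_match_unbiased(self, rng):
        n = 4
        X = rng.normal(size=(n, 6))
        Dtop = np.abs(rng.integers(0, 4, size=(n, n))).astype(float)
        Dtop = (Dtop + Dtop.T) / 2
        np.fill_diagonal(Dtop, 0.0)
        p_bias = ret.RetentionParams.create(6, 3, np.random.default_rng(0), use_bias=True)
        p_none = ret.RetentionParams.create(6, 3, np.random.default_rng(0), use_bias=False)
        out_zero = ret.biased_multihead_retention(X, _zero_bias_mats(n), p_bias, Dtop)
        out_none = ret.biased_multihead_retention(X, None, p_none, Dtop)
        assert np.abs(out_zero - out_none).max() < 1e-12

    def test_hand_computed_two_atom_instance(self):
        """3 heads, head_dim 1, identity-like weights, evaluated step by step."""
        X = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        W = np.eye(3)
        gammas = np.array([0.5, 0.5, 0.5])
        mats = _zero_bias_mats(2)
        mats.A_scaled[0, 1] = mats.A_scaled[1, 0] = 1.0
        Dtop = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = ret.RetentionParams(n_heads=3, head_dim=1, gammas=gammas,
                                Wq=W, Wk=W, Wv=W, Wo=np.eye(3),
                                bias_assignment=("adjacency", "distance", "coulomb"),
                                n_groups=3)
        got = ret.biased_multihead_retention(X, mats, p, Dtop)
        # brute force per head: scores = QK^T + B; out = (scores*gamma^D) V
        expected_heads = []
        for h, name in enumerate(("A_scaled", "Dtop_scaled", "C_scaled")):
            Qh = X @ W[:, h:h + 1]
            scores = Qh @ Qh.T + getattr(mats, name)
            expected_heads.append((scores * 0.5 ** Dtop) @ Qh)
        concat = np.concatenate(expected_heads, axis=1)
        expected = ret.group_normalize(concat, 3) @ np.eye(3)
        assert np.abs(got - expected).max() < 1e-12

    def test_output_shape_matches_input(self, rng, molecules50):
        for smi in molecules50[:5]:
            mats = interatomic_matrices(parse_molecule(smi))
            n = mats.A.shape[0]
            X = rng.normal(size=(n, 12))
            p = ret.RetentionParams.create(12, 6, rng)
            out = ret.biased_multihead_retention(X, mats, p, mats.Dtop)
            assert out.shape == (n, 12)

    def test_permutation_equivariance(self, rng):
        mats = interatomic_matrices(parse_molecule("CC(O)CCN"))
        n = mats.A.shape[0]
        X = rng.normal(size=(n, 12))
        p = ret.RetentionParams.create(12, 6, rng)
        out = ret.biased_multihead_retention(X, mats, p, mats.Dtop)
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        mats_p = InterAtomicMatrices(
            A=P @ mats.A @ P.T, Dtop=P @ mats.Dtop @ P.T, C=P @ mats.C @ P.T,
            A_scaled=P @ mats.A_scaled @ P.T, Dtop_scaled=P @ mats.Dtop_scaled @ P.T,
            C_scaled=P @ mats.C_scaled @ P.T)
        out_p = ret.biased_multihead_retention(X[perm], mats_p, p,
                                               mats_p.Dtop)
        assert np.abs(out_p - out[perm]).max() < 1e-5

    def test_missing_matrices_raise_configuration_error(self, rng):
        p = ret.RetentionParams.create(6, 3, rng, use_bias=True)
        with pytest.raises(ValueError, match="requires"):
            ret.biased_multihead_retention(np.ones((2, 6)), None, p,
                                           np.zeros((2, 2)))


class TestAttentionFallback:
    def test_rows_mix_to_convexity(self, rng):
        """Softmax weights are a convex combination: constant V stays constant."""
        n = 5
        X = rng.normal(size=(n, 6))
        p = ret.RetentionParams.create(6, 3, rng, use_bias=False)
        p2 = ret.RetentionParams(n_heads=3, head_dim=2, gammas=p.gammas,
                                 Wq=p.Wq, Wk=p.Wk,
                                 Wv=np.zeros((6, 6)), Wo=p.Wo,
                                 bias_assignment=p.bias_assignment, n_groups=3)
        out = ret.biased_multihead_attention(X, None, p2, np.zeros((n, n)))
        assert np.all(np.isfinite(out))

    def test_tensor_path_matches_numpy_path(self, rng):
        X = rng.normal(size=(4, 6))
        p = ret.RetentionParams.create(6, 3, rng, use_bias=False)
        Dtop = np.zeros((4, 4))
        a = ret.biased_multihead_attention(X, None, p, Dtop)
        b = ret.biased_multihead_attention(Tensor(X), None, p, Dtop).data
        assert np.abs(a - b).max() < 1e-12
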