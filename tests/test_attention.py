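"""Attention semantics: hand oracles, normalization invariants, complexity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eafcn import (ExternalAttentionParams, SelfAttentionParams, double_normalize,
                   ea_forward, ea_mac_count, ea_scores, init_external_attention,
                   init_self_attention, sa_attention_matrix, sa_forward, sa_mac_count,
                   softmax_normalize)
from eafcn.attention import ExternalAttention3d, SelfAttention3d


def small_sa_params(gamma=0.0):
    # C = 1, C' = 1, scalar weights chosen by hand
    return SelfAttentionParams(
        Wf=np.array([[2.0]]), Wg=np.array([[1.0]]), Wh=np.array([[1.0]]),
        Wv=np.array([[1.0]]), gamma=gamma)


class TestSelfAttention:
    def test_zero_features_give_uniform_attention(self):
        F = np.zeros((3, 2, 2, 2))
        p = init_self_attention(3, rng=np.random.default_rng(0))
        beta = sa_attention_matrix(F, p)
        np.testing.assert_allclose(beta, 1.0 / 8, atol=1e-12)

    def test_two_pixel_hand_softmax(self):
        # N=2, C=1: x = [1, 3]; f = 2x, g = x; s_ij = f_i * g_j
        F = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        p = small_sa_params()
        s = np.array([[2.0 * 1 * 1, 2.0 * 1 * 3], [2.0 * 3 * 1, 2.0 * 3 * 3]])
        expect = np.exp(s) / np.exp(s).sum(axis=0, keepdims=True)  # normalize over i
        beta = sa_attention_matrix(F, p)
        np.testing.assert_allclose(beta, expect.T, rtol=1e-12)

    def test_rows_sum_to_one(self, rng):
        F = rng.standard_normal((4, 2, 3, 2))
        p = init_self_attention(4, rng=rng)
        beta = sa_attention_matrix(F, p)
        np.testing.assert_allclose(beta.sum(axis=1), 1.0, atol=1e-6)

    def test_gamma_zero_is_identity(self, rng):
        F = rng.standard_normal((5, 2, 2, 2))
        p = init_self_attention(5, rng=rng)
        assert p.gamma == 0.0
        np.testing.assert_array_equal(sa_forward(F, p), F)

    def test_hand_forward_gamma_one(self):
        F = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        p = small_sa_params(gamma=1.0)
        beta = sa_attention_matrix(F, p)
        h = F.reshape(1, 2)                          # Wh = 1
        O = np.array([beta[j] @ h[0] for j in range(2)])  # Wv = 1
        np.testing.assert_allclose(sa_forward(F, p).ravel(), O + F.ravel(), rtol=1e-12)

    def test_output_linear_in_gamma(self, rng):
        F = rng.standard_normal((3, 2, 2, 2))
        p1 = init_self_attention(3, rng=np.random.default_rng(1))
        d1 = sa_forward(F, SelfAttentionParams(p1.Wf, p1.Wg, p1.Wh, p1.Wv, 1.0)) - F
        d2 = sa_forward(F, SelfAttentionParams(p1.Wf, p1.Wg, p1.Wh, p1.Wv, 2.0)) - F
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-10, atol=1e-12)


class TestExternalAttention:
    def test_zero_features_zero_scores(self):
        p = init_external_attention(3, k=4, rng=np.random.default_rng(0))
        scores = ea_scores(np.zeros((3, 2, 2, 2)), p)
        assert scores.shape == (8, 4)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_hand_2x2_scores(self):
        # N=2, C=C'=1, identity transform, Mk = [[2],[−1]]
        p = ExternalAttentionParams(
            Win=np.array([[1.0]]), Wout=np.array([[1.0]]),
            Mk=np.array([[2.0], [-1.0]]), Mv=np.array([[1.0], [1.0]]),
            bin=np.zeros(1), bout=np.zeros(1))
        F = np.array([3.0, -1.0]).reshape(1, 1, 1, 2)
        np.testing.assert_allclose(ea_scores(F, p), [[6.0, -3.0], [-2.0, 1.0]], rtol=1e-12)

    def test_scores_linear_in_features(self, rng):
        p = init_external_attention(2, k=3, rng=rng)
        p = ExternalAttentionParams(p.Win, p.Wout, p.Mk, p.Mv,
                                    bin=np.zeros_like(p.bin), bout=p.bout)
        F = rng.standard_normal((2, 2, 1, 2))
        np.testing.assert_allclose(ea_scores(3.0 * F, p), 3.0 * ea_scores(F, p), rtol=1e-10)

    def test_output_shape_preserved(self, rng):
        F = rng.standard_normal((8, 3, 3, 3))
        p = init_external_attention(8, k=16, rng=rng)
        assert ea_forward(F, p).shape == F.shape

    def test_zero_memory_zero_output(self, rng):
        F = rng.standard_normal((4, 2, 2, 2))
        p = init_external_attention(4, k=8, rng=rng)
        p = ExternalAttentionParams(p.Win, p.Wout, p.Mk, np.zeros_like(p.Mv),
                                    bin=p.bin, bout=np.zeros_like(p.bout))
        np.testing.assert_allclose(ea_forward(F, p), 0.0, atol=1e-12)

    def test_single_pixel_direct_evaluation(self, rng):
        # N=1: the attention row is a probability vector over memories
        p = init_external_attention(3, k=5, rng=np.random.default_rng(4))
        F = rng.standard_normal((3, 1, 1, 1))
        A = ea_scores(F, p)
        An = double_normalize(A)
        assert An.shape == (1, 5)
        assert An.min() >= 0 and An.sum() == pytest.approx(1.0)
        expect = (p.Wout @ (An @ p.Mv).T) + p.bout[:, None]
        np.testing.assert_allclose(ea_forward(F, p).ravel(), expect.ravel(), rtol=1e-10)


class TestNormalization:
    def test_zero_matrix_double_norm_uniform_rows(self):
        out = double_normalize(np.zeros((2, 2)))
        np.testing.assert_allclose(out, 0.5)

    def test_softmax_norm_zero_matrix(self):
        out = softmax_normalize(np.zeros((4, 3)))
        np.testing.assert_allclose(out, 0.25)

    def test_hand_log_matrix(self):
        A = np.log(np.array([[1.0, 3.0], [3.0, 1.0]]))
        step1 = softmax_normalize(A)
        np.testing.assert_allclose(step1, [[0.25, 0.75], [0.75, 0.25]], rtol=1e-12)
        # rows already sum to 1 -> step 2 is a no-op
        np.testing.assert_allclose(double_normalize(A), step1, rtol=1e-12)

    def test_softmax_equals_step_one_of_double(self, rng):
        A = rng.standard_normal((6, 4))
        step1 = softmax_normalize(A)
        rows = step1 / np.abs(step1).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(double_normalize(A), rows, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
    def test_normalization_sums(self, n, k, seed):
        A = np.random.default_rng(seed).standard_normal((n, k)) * 10
        np.testing.assert_allclose(softmax_normalize(A).sum(axis=0), 1.0, atol=1e-6)
        dn = double_normalize(A)
        np.testing.assert_allclose(dn.sum(axis=1), 1.0, atol=1e-6)
        assert dn.min() >= 0

    def test_double_norm_column_shift_invariance(self, rng):
        A = rng.standard_normal((5, 3))
        shifted = A.copy()
        shifted[:, 1] += 7.3
        np.testing.assert_allclose(double_normalize(shifted), double_normalize(A), rtol=1e-9)

    def test_many_random_maps_row_sums(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            A = rng.standard_normal((4, 3)) * rng.uniform(0.1, 30)
            np.testing.assert_allclose(double_normalize(A).sum(axis=1), 1.0, atol=1e-6)


class TestComplexity:
    def test_ea_linear_sa_quadratic_in_pixels(self):
        C = 16
        Ns = [8, 64, 512]
        ea = [ea_mac_count(N, C, k=64) for N in Ns]
        sa = [sa_mac_count(N, C) for N in Ns]
        # growth exponents over the 64x N range: EA ~ N^1, SA -> N^2
        ea_exp = np.log(ea[2] / ea[0]) / np.log(Ns[2] / Ns[0])
        sa_exp = np.log(sa[2] / sa[1]) / np.log(Ns[2] / Ns[1])
        assert ea_exp == pytest.approx(1.0, abs=0.01)
        assert sa_exp > 1.5
        # per-pixel EA cost is flat; the N x N attention matrix alone is
        # exactly quadratic
        assert ea[2] / Ns[2] == pytest.approx(ea[0] / Ns[0], rel=0.01)
        cr = 2  # ceil(16 / 8)
        matrix_macs = [N * N * cr for N in Ns]
        assert matrix_macs[2] / matrix_macs[0] == (Ns[2] / Ns[0]) ** 2


class TestTrainableLayers:
    def test_layer_matches_functional_ea(self, rng):
        layer = ExternalAttention3d(3, k=4, rng=np.random.default_rng(5), dtype=np.float64)
        F = rng.standard_normal((3, 2, 2, 2))
        np.testing.assert_allclose(layer.forward(F[None])[0],
                                   ea_forward(F, layer.as_params()), rtol=1e-12)

    def test_layer_matches_functional_sa(self, rng):
        layer = SelfAttention3d(3, rng=np.random.default_rng(6), dtype=np.float64)
        layer.gamma.data = np.asarray(0.8)
        F = rng.standard_normal((3, 2, 2, 2))
        np.testing.assert_allclose(layer.forward(F[None])[0],
                                   sa_forward(F, layer.as_params()), rtol=1e-12)

    def test_sa_layer_starts_as_identity(self, rng):
        layer = SelfAttention3d(4, rng=np.random.default_rng(7))
        x = rng.standard_normal((2, 4, 2, 2, 2)).astype(np.float32)
        np.testing.assert_array_equal(layer.forward(x), x)

    @pytest.mark.parametrize("mode", ["softmax", "double"])
    def test_ea_layer_gradients(self, mode, rng):
        from test_nn import check_layer_grads
        layer = ExternalAttention3d(3, k=4, norm_mode=mode,
                                    rng=np.random.default_rng(8), dtype=np.float64)
        x = rng.standard_normal((2, 3, 2, 2, 2))
        check_layer_grads(layer, x, rtol=1e-4, atol=1e-6)

    def test_sa_layer_gradients(self, rng):
        from test_nn import check_layer_grads
        layer = SelfAttention3d(3, rng=np.random.default_rng(9), dtype=np.float64)
        layer.gamma.data = np.asarray(0.6)
        x = rng.standard_normal((2, 3, 2, 2, 2))
        check_layer_grads(layer, x, rtol=1e-4, atol=1e-6)
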