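"""Encoder: attention formula oracles, row-stochasticity, fusion arithmetic,
ASPP contracts, permutation equivariance and the empty-pipeline identity."""

import numpy as np
import pytest
from scipy.special import softmax

from delicacynet.autodiff import Tensor
from delicacynet.encoder import (
    ASPPModule,
    AttentionParams,
    Encoder,
    EncoderConfig,
    aspp,
    encoder_forward,
    focused_attention,
    independent_attention,
    linear_projection,
    mhsa_fuse,
)


def make_params(d, rng=None, identity=False):
    if identity:
        mats = [np.eye(d)] * 7
    else:
        mats = [rng.standard_normal((d, d)) for _ in range(7)]
    return AttentionParams(*mats, alpha=0.5, beta=0.5, dk=d)


class TestLinearProjection:
    def test_identity_weights_return_input(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        for out in linear_projection(X, make_params(2, identity=True)):
            np.testing.assert_array_equal(out, X)

    def test_scaled_identity(self):
        p = AttentionParams(2 * np.eye(2), *[np.eye(2)] * 6, dk=2)
        q = linear_projection(np.array([[1.0, 1.0]]), p)[0]
        np.testing.assert_array_equal(q, [[2.0, 2.0]])

    def test_matches_matmul_oracle(self, rng):
        X = rng.standard_normal((3, 2))
        p = make_params(2, rng)
        outs = linear_projection(X, p)
        mats = [p.Wq, p.Wk, p.Wv, p.Wq_global, p.Wk_global, p.Wv_global]
        for out, m in zip(outs, mats):
            np.testing.assert_allclose(out, X @ m, atol=1e-12)

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            linear_projection(np.ones((2, 3)), make_params(2, rng))


class TestScaledDotProductAttention:
    def test_single_token_returns_value(self, rng):
        q, k, v = rng.standard_normal((3, 1, 4))
        np.testing.assert_allclose(focused_attention(q, k, v, 4), v)

    def test_identity_two_by_two(self):
        eye = np.eye(2)
        out = focused_attention(eye, eye, eye, dk=2)
        e = np.exp(1 / np.sqrt(2))
        p = e / (1 + e)
        np.testing.assert_allclose(out, [[p, 1 - p], [1 - p, p]], atol=1e-12)
        np.testing.assert_allclose(out[0], [0.6698, 0.3302], atol=1e-3)

    def test_identical_keys_average_values(self, rng):
        q = rng.standard_normal((4, 3))
        k = np.tile(rng.standard_normal(3), (4, 1))
        v = rng.standard_normal((4, 3))
        np.testing.assert_allclose(
            focused_attention(q, k, v, 3), np.tile(v.mean(axis=0), (4, 1)), atol=1e-12
        )

    def test_independent_equals_focused_formula(self, rng):
        q, k, v = rng.standard_normal((3, 4, 3))
        np.testing.assert_array_equal(
            independent_attention(q, k, v, 3), focused_attention(q, k, v, 3)
        )

    def test_matches_brute_force_oracle(self, rng):
        q, k, v = rng.standard_normal((3, 4, 3))
        scores = np.array([[q[i] @ k[j] / np.sqrt(3) for j in range(4)] for i in range(4)])
        expected = softmax(scores, axis=1) @ v
        np.testing.assert_allclose(focused_attention(q, k, v, 3), expected, atol=1e-12)

    def test_row_stochastic_weights(self, rng):
        for _ in range(50):
            q, k = rng.standard_normal((2, 5, 3))
            w = softmax(q @ k.T / np.sqrt(3), axis=-1)
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
            assert (w >= 0).all() and (w <= 1).all()

    def test_permutation_equivariance(self, rng):
        q, k, v = rng.standard_normal((3, 6, 4))
        perm = rng.permutation(6)
        out = focused_attention(q, k, v, 4)
        out_p = focused_attention(q[perm], k, v, 4)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


class TestMHSAFuse:
    def test_alpha_only_returns_C(self, rng):
        C, I = rng.standard_normal((2, 3, 2))
        p = AttentionParams(*[np.eye(2)] * 7, alpha=1.0, beta=0.0, dk=2)
        np.testing.assert_allclose(mhsa_fuse(C, I, p), C)

    def test_equal_weights_average(self):
        p = AttentionParams(*[np.eye(1)] * 7, alpha=0.5, beta=0.5, dk=1)
        np.testing.assert_allclose(mhsa_fuse([[2.0]], [[4.0]], p), [[3.0]])

    def test_homogeneity(self, rng):
        C, I = rng.standard_normal((2, 3, 2))
        p = make_params(2, rng)
        np.testing.assert_allclose(mhsa_fuse(3.0 * C, 3.0 * I, p), 3.0 * mhsa_fuse(C, I, p))


class TestASPP:
    def test_zero_weights_zero_output(self, rng):
        m = ASPPModule(2, 3, rates=(1, 2), rng=rng)
        for p in m.parameters():
            p.data = np.zeros_like(p.data)
        out = aspp(rng.standard_normal((2, 5, 5)), m)
        np.testing.assert_array_equal(out, np.zeros((3, 5, 5)))

    def test_single_rate_identity_fuse_is_plain_conv(self, rng):
        """One rate-1 branch with the fuse picking that branch reproduces a
        direct 3x3 convolution."""
        m = ASPPModule(1, 1, rates=(1,), rng=rng)
        kernel = rng.standard_normal((1, 1, 3, 3))
        m.branch_w[0].data = kernel
        m.branch_b[0].data = np.zeros(1)
        m.point_w.data = np.zeros_like(m.point_w.data)
        m.point_b.data = np.zeros(1)
        m.fuse_w.data = np.array([[[[1.0]], [[0.0]]]])  # select the 3x3 branch
        m.fuse_b.data = np.zeros(1)

        x = rng.standard_normal((1, 6, 6))
        xp = np.zeros((1, 8, 8))
        xp[:, 1:7, 1:7] = x
        expected = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = np.sum(kernel[0, 0] * xp[0, i : i + 3, j : j + 3])
        np.testing.assert_allclose(aspp(x, m)[0], expected, atol=1e-10)

    @pytest.mark.parametrize("rates", [(1,), (1, 2), (1, 6, 12, 18)])
    def test_spatial_dims_preserved(self, rates, rng):
        m = ASPPModule(3, 4, rates=rates, rng=rng)
        assert aspp(rng.standard_normal((3, 7, 9)), m).shape == (4, 7, 9)


class TestEncoderStack:
    def test_empty_pipeline_is_identity(self, rng):
        """L=0 layers, ASPP wired to identity, zero residual projection."""
        cfg = EncoderConfig(layers=0, width=2, n_heads=1, aspp_rates=(1,),
                            token_pool=1, positional=False, out_channels=2)
        enc = Encoder(cfg, rng, grid=(4, 4))
        for w in (enc.aspp.branch_w[0], enc.aspp.point_w):
            w.data = np.zeros_like(w.data)
        enc.aspp.point_w.data = np.eye(2)[:, :, None, None]
        enc.aspp.fuse_w.data = np.concatenate(
            [np.zeros((2, 2, 1, 1)), np.eye(2)[:, :, None, None]], axis=1
        )
        for b in (enc.aspp.branch_b[0], enc.aspp.point_b, enc.aspp.fuse_b, enc.res_b):
            b.data = np.zeros_like(b.data)
        enc.res_w.data = np.zeros_like(enc.res_w.data)

        x = rng.standard_normal((1, 2, 4, 4))
        original = rng.random((1, 4, 4, 3))
        out = enc(Tensor(x), original)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_residual_path_adds_projected_image(self, rng):
        cfg = EncoderConfig(layers=0, width=2, n_heads=1, aspp_rates=(1,),
                            token_pool=1, positional=False, out_channels=2)
        x = rng.standard_normal((1, 2, 4, 4))
        original = rng.random((1, 4, 4, 3))

        enc = Encoder(cfg, rng, grid=(4, 4))
        enc.res_w.data = np.zeros_like(enc.res_w.data)
        enc.res_b.data = np.zeros_like(enc.res_b.data)
        zero = enc(Tensor(x), original).data
        enc.res_w.data = rng.standard_normal(enc.res_w.shape)
        nonzero = enc(Tensor(x), original).data
        from delicacynet.autodiff import conv2d

        proj = conv2d(Tensor(np.moveaxis(original, -1, 1)), Tensor(enc.res_w.data),
                      Tensor(enc.res_b.data)).data
        np.testing.assert_allclose(nonzero - zero, proj, atol=1e-10)

    def test_forward_deterministic_and_shape(self, rng):
        cfg = EncoderConfig(layers=1, width=4, n_heads=2, aspp_rates=(1, 2),
                            token_pool=2, out_channels=4)
        enc = Encoder(cfg, rng, grid=(4, 4))
        x = rng.standard_normal((2, 4, 4, 4))
        original = rng.random((2, 4, 4, 3))
        a = enc(Tensor(x), original).data
        b = enc(Tensor(x), original).data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (2, 4, 2, 2)

    def test_single_sample_wrapper(self, rng):
        cfg = EncoderConfig(layers=1, width=4, n_heads=1, aspp_rates=(1,),
                            token_pool=1, out_channels=4)
        enc = Encoder(cfg, rng, grid=(3, 3))
        out = encoder_forward(rng.standard_normal((4, 3, 3)), rng.random((3, 3, 3)), enc)
        assert out.shape == (4, 3, 3)

    def test_beta_zero_single_path_layer(self, rng):
        """With beta=0 the dual-path fusion reduces to the focused path: the
        independent-attention parameters stop influencing the output."""
        from delicacynet.encoder import EncoderLayer

        layer = EncoderLayer(4, 1, 2, rng)
        layer.beta.data = np.array(0.0)
        x = Tensor(rng.standard_normal((1, 5, 4)))
        base = layer(x).data
        layer.Wqg.data = rng.standard_normal((4, 4))
        layer.Wvg.data = rng.standard_normal((4, 4))
        np.testing.assert_allclose(layer(x).data, base, atol=1e-12)
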