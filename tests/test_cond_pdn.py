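"""Mass-track network: shape ladder, contrast operator, separable conv,
threshold semantics — each composite checked against a brute-force oracle."""

import numpy as np
import pytest

from vhucsnet.autodiff import Tensor, no_grad
from vhucsnet.cond_pdn import (PDN, PDNConfig, contrast_delta,
                               desk_pdn_config)
from vhucsnet.layers import max_pool2


def brute_max_pool2(x):
    n, c, h, w = x.shape
    out = np.empty((n, c, h // 2, w // 2), dtype=x.dtype)
    for i in range(h // 2):
        for j in range(w // 2):
            out[:, :, i, j] = x[:, :, 2 * i : 2 * i + 2,
                                2 * j : 2 * j + 2].max(axis=(2, 3))
    return out


def brute_local_average(x):
    """3x3 neighbourhood mean with partial windows at the border."""
    n, c, h, w = x.shape
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            ys = slice(max(i - 1, 0), min(i + 2, h))
            xs = slice(max(j - 1, 0), min(j + 2, w))
            out[:, :, i, j] = x[:, :, ys, xs].mean(axis=(2, 3))
    return out


class TestConfig:
    def test_fused_channel_arithmetic(self):
        cfg = PDNConfig()
        assert cfg.fused_channels == 1536  # 1024 + 512
        assert cfg.stage_targets() == [128, 256, 512, 1024]

    def test_desk_ladder(self):
        cfg = desk_pdn_config()
        assert cfg.widths[0] == 16
        assert cfg.stage_targets() == [32, 64, 256]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PDNConfig(threshold=1.5)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            PDNConfig(input_size=(100, 100))


class TestOperators:
    def test_delta_annihilates_constants(self):
        for value in (0.0, 1.0, -3.5):
            x = Tensor(np.full((2, 3, 8, 8), value, dtype=np.float32))
            np.testing.assert_allclose(contrast_delta(x).data, 0.0, atol=1e-5)

    def test_delta_single_bright_pixel_matches_pooling_oracle(self):
        x = np.zeros((1, 1, 8, 8), dtype=np.float32)
        x[0, 0, 3, 4] = 5.0
        got = contrast_delta(Tensor(x)).data
        expect = x - brute_local_average(x)
        np.testing.assert_allclose(got, expect, atol=1e-5)
        # response confined to the pixel's 3x3 neighbourhood
        outside = np.ones((8, 8), dtype=bool)
        outside[2:5, 3:6] = False
        assert np.abs(got[0, 0][outside]).max() < 1e-6

    def test_max_pool_matches_brute_force(self, rng):
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        got = max_pool2(Tensor(x)).data
        np.testing.assert_allclose(got, brute_max_pool2(x), atol=0)

    def test_separable_conv_equals_two_step_oracle(self, rng):
        cfg = desk_pdn_config()
        pdn = PDN(cfg, seed=0)
        c = cfg.contrast
        x = rng.normal(size=(1, c, 4, 4)).astype(np.float32)
        with no_grad():
            got = pdn.sep_pointwise(pdn.sep_depthwise(Tensor(x))).data
        # oracle: explicit depthwise pass then explicit channel mixing
        dw_w = pdn.sep_depthwise.weight.data
        dw_b = pdn.sep_depthwise.bias.data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        depth = np.zeros_like(x)
        for ch in range(c):
            for i in range(4):
                for j in range(4):
                    depth[0, ch, i, j] = (
                        xp[0, ch, i : i + 3, j : j + 3] * dw_w[ch]).sum()
        depth += dw_b[None, :, None, None]
        pw_w = pdn.sep_pointwise.weight.data[:, :, 0, 0]
        oracle = np.einsum("nchw,oc->nohw", depth, pw_w) + \
            pdn.sep_pointwise.bias.data[None, :, None, None]
        np.testing.assert_allclose(got, oracle, rtol=1e-3, atol=1e-4)


class TestShapesAndHead:
    @pytest.fixture()
    def desk_pdn(self):
        return PDN(desk_pdn_config(), seed=0)

    def test_stem_shape_and_range(self, desk_pdn, rng):
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        with no_grad():
            out = desk_pdn.pdn_stem(x)
        assert tuple(out.shape) == (1, 16, 64, 64)
        assert (out.data >= 0).all()

    def test_stem_zero_image_zero_output(self):
        pdn = PDN(desk_pdn_config(), seed=5)
        pdn.stem_conv.bias.data[:] = 0.0
        x = Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32))
        with no_grad():
            out = pdn.pdn_stem(x)
        assert np.allclose(out.data, 0.0, atol=1e-5)

    def test_desk_contrast_ladder(self, desk_pdn, rng):
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        with no_grad():
            f = desk_pdn.pdn_stem(x)
            c = desk_pdn.multiscale_contrast(f)
            b = desk_pdn.boundary_refine(c)
            prob, mask = desk_pdn.pdn_head(b, c, (64, 64))
        assert tuple(c.shape) == (1, 256, 8, 8)
        assert tuple(b.shape) == (1, 128, 8, 8)
        assert tuple(prob.shape) == (1, 1, 64, 64)
        assert mask.shape == (1, 64, 64)

    def test_leaky_slope_definition(self):
        from vhucsnet.autodiff import leaky_relu

        out = leaky_relu(Tensor(np.array([-1.0], dtype=np.float32)), 0.01)
        assert out.data[0] == pytest.approx(-0.01)

    def test_head_tie_rule_and_monotonicity(self, rng):
        cfg = desk_pdn_config()
        pdn = PDN(cfg, seed=0)
        pdn.head_conv.weight.data[:] = 0.0
        pdn.head_conv.bias.data[:] = 0.0
        c = Tensor(rng.random((1, cfg.contrast, 8, 8)).astype(np.float32))
        b = Tensor(rng.random((1, cfg.border, 8, 8)).astype(np.float32))
        with no_grad():
            prob, mask = pdn.pdn_head(b, c, (64, 64))
        np.testing.assert_allclose(prob.data, 0.5, atol=1e-7)
        assert (mask == 0).all()  # strict > tau at tau = 0.5

    def test_raising_threshold_never_adds_pixels(self, rng):
        cfg = desk_pdn_config()
        pdn = PDN(cfg, seed=3)
        pdn.eval()
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        masks = []
        for tau in (0.3, 0.5, 0.7):
            pdn.cfg.threshold = tau
            with no_grad():
                _, mask = pdn(x)
            masks.append(mask)
        assert (masks[1] <= masks[0]).all()
        assert (masks[2] <= masks[1]).all()

    def test_branch_spatial_mismatch_rejected(self, desk_pdn, rng):
        c = Tensor(rng.random((1, 256, 8, 8)).astype(np.float32))
        b = Tensor(rng.random((1, 128, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="spatial"):
            desk_pdn.pdn_head(b, c, (64, 64))


def test_full_scale_ladder_prints_published_shapes(rng):
    """256x256 input: 16x16x1024 contrast -> 16x16x1536 fused -> 16x16x1."""
    pdn = PDN(PDNConfig(), seed=0)
    x = Tensor(rng.random((1, 1, 256, 256)).astype(np.float32))
    with no_grad():
        f = pdn.pdn_stem(x)
        c = pdn.multiscale_contrast(f)
        b = pdn.boundary_refine(c)
        assert tuple(c.shape) == (1, 1024, 16, 16)
        assert tuple(b.shape) == (1, 512, 16, 16)
        from vhucsnet import autodiff as ad
        fused = ad.concat([c, b], axis=1)
        assert tuple(fused.shape) == (1, 1536, 16, 16)
        prob, _ = pdn.pdn_head(b, c, (16, 16))
    assert tuple(prob.shape) == (1, 1, 16, 16)
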