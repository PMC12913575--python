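"""Organ-track network: shape contracts, block semantics, learning smoke."""

import numpy as np
import pytest

from vhucsnet import autodiff as ad
from vhucsnet.autodiff import Tensor, no_grad
from vhucsnet.layers import Conv2d
from vhucsnet.vhu_net import (HRNetBlock, PatchEmbed, VHUNet, VHUNetConfig,
                              ViTBlock, count_parameters, desk_config,
                              model_size_mib)


@pytest.fixture(scope="module")
def desk_net():
    return VHUNet(desk_config(), seed=0)


def rand_feature(rng, n, c, h, w):
    return Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


class TestConfig:
    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            VHUNetConfig(input_size=(100, 100))

    def test_width_divisor_scales_contracts(self):
        cfg = desk_config()
        assert cfg.widths == (16, 32, 64, 128)
        assert cfg.bridge == 256
        assert cfg.stage_shapes() == [(32, 32, 16), (16, 16, 32),
                                      (8, 8, 64), (4, 4, 128)]

    def test_default_stage_shapes_match_printed_ladder(self):
        shapes = VHUNetConfig().stage_shapes()
        assert shapes == [(112, 112, 64), (56, 56, 128),
                          (28, 28, 256), (14, 14, 512)]

    def test_channel_doubling(self):
        widths = VHUNetConfig().widths
        assert all(b == 2 * a for a, b in zip(widths, widths[1:]))


class TestPatchEmbed:
    def test_patchwise_linear_map_oracle(self):
        """With an identity-like kernel and zero positional table, each
        output cell is the known linear combination of its 2x2 patch."""
        cfg = VHUNetConfig(input_size=(4, 4), in_channels=1, embed_dim=4,
                           stage_widths=(4,), attn_heads=1, patch_size=2)
        rng = np.random.default_rng(0)
        pe = PatchEmbed(cfg, rng)
        pe.pos.data[:] = 0.0
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        out = pe(Tensor(x)).data
        w = pe.proj.weight.data  # (4, 1, 2, 2)
        for oy in range(2):
            for ox in range(2):
                patch = x[0, 0, 2 * oy : 2 * oy + 2, 2 * ox : 2 * ox + 2]
                expect = (w[:, 0] * patch).sum(axis=(1, 2)) + pe.proj.bias.data
                np.testing.assert_allclose(out[0, :, oy, ox], expect,
                                           rtol=1e-5)

    def test_zero_image_zero_kernel_path(self):
        cfg = desk_config()
        pe = PatchEmbed(cfg, np.random.default_rng(0))
        pe.proj.bias.data[:] = 0.0
        pe.pos.data[:] = 0.0
        out = pe(Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert (out.data == 0).all()

    def test_homogeneity_with_zero_bias(self, rng):
        cfg = desk_config()
        pe = PatchEmbed(cfg, np.random.default_rng(1))
        pe.proj.bias.data[:] = 0.0
        pe.pos.data[:] = 0.0
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        a = pe(Tensor(x)).data
        b = pe(Tensor(3.0 * x)).data
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-4, atol=1e-5)


class TestViTBlock:
    def test_residual_identity_with_zeroed_outputs(self, rng):
        cfg = desk_config()
        stack = [ViTBlock(16, cfg, np.random.default_rng(s)) for s in range(3)]
        for blk in stack:
            blk.proj.weight.data[:] = 0.0
            blk.proj.bias.data[:] = 0.0
            blk.fc2.weight.data[:] = 0.0
            blk.fc2.bias.data[:] = 0.0
        x = rand_feature(rng, 2, 16, 8, 8)
        out = x
        for blk in stack:
            out = blk(out)
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_shape_preserving(self, rng):
        cfg = desk_config(attn_heads=4)
        blk = ViTBlock(8, cfg, np.random.default_rng(0))
        assert blk(rand_feature(rng, 1, 8, 2, 2)).shape == (1, 8, 2, 2)

    def test_token_permutation_equivariance(self, rng):
        """Without positional information inside the block, permuting the
        four tokens commutes with the block."""
        cfg = desk_config(attn_heads=2)
        blk = ViTBlock(8, cfg, np.random.default_rng(3))
        x = rng.normal(size=(1, 8, 2, 2)).astype(np.float32)
        perm = [2, 0, 3, 1]  # token permutation on the flattened 2x2 grid
        xt = x.reshape(1, 8, 4)
        x_perm = xt[:, :, perm].reshape(1, 8, 2, 2)
        out = blk(Tensor(x)).data.reshape(1, 8, 4)
        out_perm = blk(Tensor(x_perm)).data.reshape(1, 8, 4)
        np.testing.assert_allclose(out_perm, out[:, :, perm], atol=1e-5)


class TestHRNetBlock:
    def test_single_scale_reduces_to_pointwise_conv(self, rng):
        cfg = desk_config(hrnet_scales=1)
        blk = HRNetBlock(4, 6, cfg, np.random.default_rng(0))
        x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        out = blk.pre_activation(Tensor(x)).data
        w = blk.conv0.weight.data[:, :, 0, 0]  # (6, 4)
        oracle = np.einsum("nchw,oc->nohw", x, w) + \
            blk.conv0.bias.data[None, :, None, None]
        np.testing.assert_allclose(out, oracle, rtol=1e-4, atol=1e-5)

    def test_zero_weights_zero_preactivation(self, rng):
        cfg = desk_config()
        blk = HRNetBlock(4, 4, cfg, np.random.default_rng(0))
        for s in range(cfg.hrnet_scales):
            conv = getattr(blk, f"conv{s}")
            conv.weight.data[:] = 0.0
            if conv.bias is not None:
                conv.bias.data[:] = 0.0
        out = blk.pre_activation(rand_feature(rng, 1, 4, 6, 6))
        assert (out.data == 0).all()

    def test_shape_contract(self, rng):
        cfg = VHUNetConfig()
        blk = HRNetBlock(512, 512, cfg, np.random.default_rng(0))
        assert blk(rand_feature(rng, 1, 512, 14, 14)).shape == (1, 512, 14, 14)


class TestFullLadder:
    def test_desk_shapes(self, desk_net, rng):
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        with no_grad():
            feats = desk_net.encode(x)
            shapes = [tuple(f.shape[1:]) for f in feats]
            assert shapes == [(16, 32, 32), (32, 16, 16), (64, 8, 8),
                              (128, 4, 4)]
            b = desk_net.bridge(feats[-1])
            assert tuple(b.shape[1:]) == (256, 4, 4)
            assert (b.data >= 0).all()  # ReLU range
            d = desk_net.decode(b, feats)
            assert tuple(d.shape[1:]) == (16, 64, 64)
            p = desk_net.kidney_head(d)
            assert tuple(p.shape[1:]) == (1, 64, 64)
            assert (p.data > 0).all() and (p.data < 1).all()

    def test_bridge_relu_clamps_negative_bias(self, desk_net, rng):
        saved = desk_net.bridge_conv.state_dict()
        desk_net.bridge_conv.weight.data[:] = 0.0
        desk_net.bridge_conv.bias.data[:] = -1.0
        with no_grad():
            out = desk_net.bridge(rand_feature(rng, 1, 128, 4, 4))
        assert (out.data == 0).all()
        desk_net.bridge_conv.load_state_dict(saved)

    def test_head_sigmoid_semantics(self, desk_net, rng):
        saved = desk_net.head.state_dict()
        feat = rand_feature(rng, 1, 16, 8, 8)
        desk_net.head.weight.data[:] = 0.0
        desk_net.head.bias.data[:] = 0.0
        with no_grad():
            assert np.allclose(desk_net.kidney_head(feat).data, 0.5)
        desk_net.head.bias.data[:] = 10.0
        with no_grad():
            assert (desk_net.kidney_head(feat).data > 0.9999).all()
        desk_net.head.load_state_dict(saved)

    def test_decoder_zero_weights_constant_output(self):
        net = VHUNet(desk_config(), seed=1)
        for name, p in net.named_parameters():
            if name.startswith("dec"):
                p.data[:] = 0.0
        rng = np.random.default_rng(0)
        feats = [Tensor(rng.normal(size=(1, c, s, s)).astype(np.float32))
                 for c, s in ((16, 32), (32, 16), (64, 8), (128, 4))]
        bridge = Tensor(rng.normal(size=(1, 256, 4, 4)).astype(np.float32))
        with no_grad():
            out = net.decode(bridge, feats).data
        assert np.allclose(out, out[0, :, :1, :1][None, :, :, :], atol=1e-7)

    def test_decoder_rejects_wrong_skip_shape(self, desk_net, rng):
        feats = [rand_feature(rng, 1, 16, 32, 32),
                 rand_feature(rng, 1, 32, 16, 16),
                 rand_feature(rng, 1, 64, 8, 8),
                 rand_feature(rng, 1, 128, 8, 8)]  # wrong spatial dims
        with pytest.raises(ValueError, match="skip"):
            with no_grad():
                desk_net.decode(rand_feature(rng, 1, 256, 4, 4), feats)


class TestParameterAccounting:
    def test_count_examples(self):
        class Empty:
            def parameters(self):
                return []

        assert count_parameters(Empty()) == 0
        conv = Conv2d(1, 8, 3, np.random.default_rng(0))
        assert count_parameters(conv) == 3 * 3 * 8 + 8
        pointwise = Conv2d(4, 4, 1, np.random.default_rng(0), bias=False)
        assert count_parameters(pointwise) == 16

    @pytest.mark.parametrize("count,mib", [
        (32624261, 124.45), (7781761, 29.69), (3370000, 12.86),
        (196916, 0.75), (0, 0.0),
    ])
    def test_fp32_size_arithmetic(self, count, mib):
        assert model_size_mib(count) == pytest.approx(mib)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            model_size_mib(-1)


def test_single_step_decreases_dice_loss_on_phantom(tiny_pairs):
    """Gradient-flow smoke: one Adam step on one phantom lowers its loss."""
    from vhucsnet.optim import Adam
    from vhucsnet.train import soft_dice_loss

    net = VHUNet(desk_config(input_size=(32, 32)), seed=0)
    pair = tiny_pairs[0]
    x = (pair.image.astype(np.float32) / 255.0)[None, None]
    y = pair.mask[None, None].astype(np.float32)
    opt = Adam(net.parameters(), lr=1e-3)
    losses = []
    for _ in range(2):
        loss = soft_dice_loss(net(Tensor(x)), y)
        losses.append(loss.item())
        net.zero_grad()
        loss.backward()
        opt.step()
    assert losses[1] < losses[0]
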