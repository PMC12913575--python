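"""Track 1: the transformer-enhanced U-Net for organ segmentation.

The encoder tokenizes the input with a non-overlapping patch embedding
(stride-P convolution plus a learned additive positional table) and runs
four stages of [ViT attention block -> HRNet multi-scale convolution block],
with stride-2 max pooling between stages.  With the default 224x224x3 input,
patch size 2 and widths 64-128-256-512, the stage outputs are

    112x112x64 -> 56x56x128 -> 28x28x256 -> 14x14x512,

a 3x3 convolution + ReLU bridge lifts the deepest stage to 14x14x1024, and
the decoder reverses the ladder with additive skip connections: at each of
four stages the matching encoder feature is 1x1-projected, added, upsampled
by a stride-2 transposed convolution, and refined by a 3x3 convolution +
ReLU, ending at 224x224x64.  A 1x1 convolution + sigmoid head yields the
per-pixel organ probability map.

Self-attention over more than `attn_token_limit` tokens is evaluated on an
average-pooled token grid and broadcast back (a CPU-scale approximation,
logged when active); the pointwise feed-forward half of the block always
runs at full resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (BatchNorm2d, Conv2d, ConvTranspose2d, LayerNorm, Linear,
                     Module, avg_pool, max_pool2, nearest_upsample,
                     scaled_dot_attention)

logger = logging.getLogger(__name__)

__all__ = ["VHUNetConfig", "VHUNet", "ViTBlock", "HRNetBlock",
           "count_parameters", "model_size_mib"]


@dataclass
class VHUNetConfig:
    input_size: tuple[int, int] = (224, 224)
    in_channels: int = 3
    patch_size: int = 2
    embed_dim: int = 64
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    bridge_width: int = 1024
    attn_heads: int = 4
    ffn_expansion: int = 2
    hrnet_scales: int = 3
    width_divisor: int = 1
    attn_token_limit: int = 4096
    attn_pool_factor: int = 4

    def __post_init__(self):
        if self.width_divisor < 1:
            raise ValueError("width_divisor must be >= 1")
        step = self.patch_size * 2 ** (len(self.stage_widths) - 1)
        if self.input_size[0] % step or self.input_size[1] % step:
            raise ValueError(
                f"input size {self.input_size} must be divisible by "
                f"patch_size * 2^(stages-1) = {step}"
            )
        if self.embed // self.attn_heads * self.attn_heads != self.embed:
            raise ValueError("embed_dim/width_divisor must be divisible by attn_heads")

    @property
    def embed(self) -> int:
        return self.embed_dim // self.width_divisor

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(w // self.width_divisor for w in self.stage_widths)

    @property
    def bridge(self) -> int:
        return self.bridge_width // self.width_divisor

    def stage_shapes(self) -> list[tuple[int, int, int]]:
        """(H, W, C) contract for each encoder stage output."""
        h, w = self.input_size
        p = self.patch_size
        return [
            (h // (p * 2 ** i), w // (p * 2 ** i), c)
            for i, c in enumerate(self.widths)
        ]


def desk_config(**overrides) -> VHUNetConfig:
    """64x64 single-channel preset for CPU-scale experiments.

    Attention pools above 256 tokens here (vs 4096 at full scale) so the
    first-stage 32x32 token grid attends at 8x8; the convolutional path
    still runs at full resolution.
    """
    params = dict(input_size=(64, 64), in_channels=1, width_divisor=4,
                  attn_token_limit=256)
    params.update(overrides)
    return VHUNetConfig(**params)


class PatchEmbed(Module):
    """Non-overlapping patch tokenization + learned positional table."""

    def __init__(self, cfg: VHUNetConfig, rng: np.random.Generator):
        super().__init__()
        p = cfg.patch_size
        self.proj = Conv2d(cfg.in_channels, cfg.embed, p, rng, stride=p, padding=0)
        h, w = cfg.input_size[0] // p, cfg.input_size[1] // p
        self.pos = Tensor(np.zeros((1, cfg.embed, h, w), dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.proj(x) + self.pos


class ViTBlock(Module):
    """LN -> multi-head self-attention -> residual, LN -> FFN -> residual."""

    def __init__(self, channels: int, cfg: VHUNetConfig, rng: np.random.Generator):
        super().__init__()
        if channels % cfg.attn_heads:
            raise ValueError("channels must be divisible by attn_heads")
        self.channels = channels
        self.heads = cfg.attn_heads
        self.token_limit = cfg.attn_token_limit
        self.pool_factor = cfg.attn_pool_factor
        self.ln1 = LayerNorm(channels)
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng)
        self.ln2 = LayerNorm(channels)
        self.fc1 = Linear(channels, cfg.ffn_expansion * channels, rng)
        self.fc2 = Linear(cfg.ffn_expansion * channels, channels, rng)
        self._pool_logged = False

    def _attend(self, tokens: Tensor, n: int, t: int) -> Tensor:
        c, h = self.channels, self.heads
        dh = c // h
        qkv = self.qkv(self.ln1(tokens))  # (N, T, 3C)
        qkv = qkv.reshape((n, t, 3, h, dh)).transpose((2, 0, 3, 1, 4))
        stacked = ad.reshape(qkv, (3, n * h, t, dh))
        q, k, v = (_index0(stacked, i) for i in range(3))
        out = scaled_dot_attention(q, k, v)  # (N*h, T, dh)
        out = out.reshape((n, h, t, dh)).transpose((0, 2, 1, 3)).reshape((n, t, c))
        return self.proj(out)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, hh, ww = x.shape
        pooled = hh * ww > self.token_limit
        if pooled:
            if not self._pool_logged:
                logger.warning(
                    "ViT block: %dx%d tokens exceed %d; attention runs on a "
                    "grid pooled by %d and is broadcast back",
                    hh, ww, self.token_limit, self.pool_factor)
                self._pool_logged = True
            f = self.pool_factor
            xa = avg_pool(x, f)
            ha, wa = hh // f, ww // f
        else:
            xa, ha, wa = x, hh, ww
        tokens = xa.reshape((n, c, ha * wa)).transpose((0, 2, 1))
        attn_out = self._attend(tokens, n, ha * wa)
        attn_map = attn_out.transpose((0, 2, 1)).reshape((n, c, ha, wa))
        if pooled:
            attn_map = nearest_upsample(attn_map, self.pool_factor)
        x = x + attn_map  # ViT(F) = MHSA(LN(F)) + F
        # FFN half is pointwise: apply over full-resolution tokens
        tokens = x.reshape((n, c, hh * ww)).transpose((0, 2, 1))
        ffn = self.fc2(ad.relu(self.fc1(self.ln2(tokens))))
        return x + ffn.transpose((0, 2, 1)).reshape((n, c, hh, ww))


def _index0(t: Tensor, i: int) -> Tensor:
    """Select t[i] along axis 0 (used to split stacked q/k/v)."""
    data = t.data[i]

    def backward(g):
        full = np.zeros_like(t.data)
        full[i] = g
        return (full,)

    return ad._make(np.ascontiguousarray(data), (t,), backward)


class HRNetBlock(Module):
    """Sum of parallel convolutions at kernel scales {1, 3, 5, ...},
    followed by batch normalization and ReLU."""

    def __init__(self, in_ch: int, out_ch: int, cfg: VHUNetConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.n_scales = cfg.hrnet_scales
        for s in range(cfg.hrnet_scales):
            setattr(self, f"conv{s}",
                    Conv2d(in_ch, out_ch, 2 * s + 1, rng, bias=(s == 0)))
        self.bn = BatchNorm2d(out_ch)

    def pre_activation(self, x: Tensor) -> Tensor:
        out = self.conv0(x)
        for s in range(1, self.n_scales):
            out = out + getattr(self, f"conv{s}")(x)
        return out

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.bn(self.pre_activation(x)))


class DecoderStage(Module):
    """skip 1x1-projection -> additive fusion -> x2 transposed-conv
    upsampling -> 3x3 convolution + ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.skip_proj = Conv2d(skip_ch, in_ch, 1, rng)
        self.up = ConvTranspose2d(in_ch, out_ch, rng)
        self.conv = Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        if x.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder stage: feature {x.shape} and skip {skip.shape} "
                "spatial dims differ")
        x = x + self.skip_proj(skip)
        return ad.relu(self.conv(self.up(x)))


class VHUNet(Module):
    """The full organ-segmentation track."""

    def __init__(self, cfg: VHUNetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.widths
        self.patch_embed = PatchEmbed(cfg, rng)
        in_ch = cfg.embed
        for i, w in enumerate(widths):
            setattr(self, f"vit{i}", ViTBlock(in_ch, cfg, rng))
            setattr(self, f"hr{i}", HRNetBlock(in_ch, w, cfg, rng))
            in_ch = w
        self.bridge_conv = Conv2d(widths[-1], cfg.bridge, 3, rng)
        in_ch = cfg.bridge
        skip_chs = widths[::-1]  # deep -> shallow
        out_chs = list(widths[::-1][1:]) + [widths[0]]
        for i, (sc, oc) in enumerate(zip(skip_chs, out_chs)):
            setattr(self, f"dec{i}", DecoderStage(in_ch, sc, oc, rng))
            in_ch = oc
        self.head = Conv2d(widths[0], 1, 1, rng)

    # -- pieces (each is independently testable) -----------------------------
    def encode(self, x: Tensor) -> list[Tensor]:
        """Run the four encoder stages; returns stage outputs shallow->deep."""
        f = self.patch_embed(x)
        feats = []
        for i in range(len(self.cfg.widths)):
            if i > 0:
                f = max_pool2(f)
            f = getattr(self, f"hr{i}")(getattr(self, f"vit{i}")(f))
            feats.append(f)
        return feats

    def bridge(self, f4: Tensor) -> Tensor:
        return ad.relu(self.bridge_conv(f4))

    def decode(self, bridge_out: Tensor, skips: list[Tensor]) -> Tensor:
        x = bridge_out
        for i, skip in enumerate(skips[::-1]):
            x = getattr(self, f"dec{i}")(x, skip)
        return x

    def kidney_head(self, decoded: Tensor) -> Tensor:
        return ad.sigmoid(self.head(decoded))

    def __call__(self, x: Tensor) -> Tensor:
        feats = self.encode(x)
        return self.kidney_head(self.decode(self.bridge(feats[-1]), feats))


def count_parameters(model: Module) -> int:
    """Exact number of learnable scalar parameters."""
    return sum(p.data.size for p in model.parameters())


def model_size_mib(param_count: int, bytes_per_param: int = 4) -> float:
    """fp32 checkpoint size in MiB, rounded half-up to 2 decimals."""
    import decimal

    if param_count < 0:
        raise ValueError("parameter count must be >= 0")
    mib = decimal.Decimal(param_count * bytes_per_param) / decimal.Decimal(1048576)
    return float(mib.quantize(decimal.Decimal("0.01"),
                              rounding=decimal.ROUND_HALF_UP))
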