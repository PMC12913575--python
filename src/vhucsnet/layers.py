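"""Neural-network building blocks on the autodiff engine.

Feature maps are carried internally in NCHW layout (batch, channels, height,
width); the public package API uses H x W x C rasters and converts at the
boundary.  Convolutions are im2col + GEMM; the transposed convolution is
restricted to kernel_size == stride (the non-overlapping x2 upsampling the
decoder uses), which keeps its adjoint trivial.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, _make, grad_enabled


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for name, _ in self.named_buffers():
            self._set_buffer(name, state[name])

    # running statistics (batch norm) -- stored outside the autodiff graph
    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in getattr(self, "_buffers", {}).items():
            yield prefix + name, val
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def _set_buffer(self, dotted: str, value: np.ndarray):
        mod = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]] = np.asarray(value, dtype=np.float32).copy()


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """He-normal initialization."""
    scale = math.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32), True)


# -- convolutions ------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    # (N, ho, wo, C*kh*kw)
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n, ho * wo, c * kh * kw), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = xshape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = kernel_size, stride
        self.padding = (kernel_size // 2) if padding is None else padding
        self.weight = _param(rng, (out_ch, in_ch, kernel_size, kernel_size),
                             in_ch * kernel_size * kernel_size)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.k, self.stride, self.padding
        w, b = self.weight, self.bias
        cols, ho, wo = _im2col(x.data, k, k, s, p)
        wmat = w.data.reshape(self.out_ch, -1)
        out = cols @ wmat.T  # (N, ho*wo, out)
        if b is not None:
            out += b.data
        n = x.data.shape[0]
        out = out.transpose(0, 2, 1).reshape(n, self.out_ch, ho, wo)
        xshape = x.data.shape

        def backward(g):
            gmat = g.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)  # (N, P, out)
            dw = np.einsum("npo,npk->ok", gmat, cols, optimize=True).reshape(w.data.shape)
            dcols = gmat @ wmat
            dx = _col2im(dcols, xshape, k, k, s, p)
            grads = [dx, dw]
            if b is not None:
                grads.append(gmat.sum(axis=(0, 1)))
            return tuple(grads)

        parents = (x, w) if b is None else (x, w, b)
        return _make(np.ascontiguousarray(out), parents, backward)


class DepthwiseConv2d(Module):
    """Per-channel (grouped) convolution; the spatial half of a separable conv."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.channels, self.k = channels, kernel_size
        self.pad = kernel_size // 2
        self.weight = _param(rng, (channels, kernel_size, kernel_size),
                             kernel_size * kernel_size)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        k, p = self.k, self.pad
        w, b = self.weight, self.bias
        xd = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xd.shape
        h, wdt = hp - 2 * p, wp - 2 * p
        out = np.zeros((n, c, h, wdt), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += w.data[None, :, i, j, None, None] * xd[:, :, i : i + h, j : j + wdt]
        out += b.data[None, :, None, None]

        def backward(g):
            dw = np.zeros_like(w.data)
            dxp = np.zeros_like(xd)
            for i in range(k):
                for j in range(k):
                    patch = xd[:, :, i : i + h, j : j + wdt]
                    dw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
                    dxp[:, :, i : i + h, j : j + wdt] += g * w.data[None, :, i, j, None, None]
            dx = dxp[:, :, p:-p, p:-p] if p else dxp
            return dx, dw, g.sum(axis=(0, 2, 3))

        return _make(out, (x, w, b), backward)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel_size == stride (exact x2 upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, factor: int = 2):
        super().__init__()
        self.in_ch, self.out_ch, self.f = in_ch, out_ch, factor
        self.weight = _param(rng, (in_ch, out_ch, factor, factor), in_ch)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        f, w, b = self.f, self.weight, self.bias
        n, c, h, wd = x.data.shape
        wmat = w.data.reshape(c, -1)  # (in, out*f*f)
        out = np.einsum("nchw,ck->nhwk", x.data, wmat, optimize=True)
        out = out.reshape(n, h, wd, self.out_ch, f, f).transpose(0, 3, 1, 4, 2, 5)
        out = out.reshape(n, self.out_ch, h * f, wd * f) + b.data[None, :, None, None]

        def backward(g):
            gr = g.reshape(n, self.out_ch, h, f, wd, f).transpose(0, 2, 4, 1, 3, 5)
            gr = gr.reshape(n, h, wd, -1)  # (N,h,w,out*f*f)
            dx = np.einsum("nhwk,ck->nchw", gr, wmat, optimize=True)
            dw = np.einsum("nchw,nhwk->ck", x.data, gr, optimize=True).reshape(w.data.shape)
            return dx, dw, g.sum(axis=(0, 2, 3))

        return _make(np.ascontiguousarray(out), (x, w, b), backward)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(q k^T / sqrt(d)) v over stacked (B, T, d) tensors.

    Fused into one op so the (B, T, T) attention matrix is materialized once
    and reused in the backward pass.
    """
    d = q.data.shape[-1]
    scale = np.float32(1.0 / math.sqrt(d))
    a = np.matmul(q.data, np.swapaxes(k.data, -1, -2))
    a *= scale
    a -= a.max(axis=-1, keepdims=True)
    np.exp(a, out=a)
    a /= a.sum(axis=-1, keepdims=True)
    out = np.matmul(a, v.data)

    def backward(g):
        dv = np.matmul(np.swapaxes(a, -1, -2), g)
        da = np.matmul(g, np.swapaxes(v.data, -1, -2))
        da -= (da * a).sum(axis=-1, keepdims=True)
        da *= a
        da *= scale
        dq = np.matmul(da, k.data)
        dk = np.matmul(np.swapaxes(da, -1, -2), q.data)
        return dq, dk, dv

    return _make(out, (q, k, v), backward)


# -- pooling and resampling --------------------------------------------------

def max_pool2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling (even spatial dims required)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))

    def backward(g):
        mask = r == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max in each window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = mask * g[:, :, :, None, :, None]
        return (dx.reshape(n, c, h, w),)

    return _make(np.ascontiguousarray(out), (x,), backward)


def avg_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling by an integer factor."""
    n, c, h, w = x.data.shape
    f = factor
    r = x.data.reshape(n, c, h // f, f, w // f, f)
    out = r.mean(axis=(3, 5))

    def backward(g):
        dx = np.broadcast_to(
            g[:, :, :, None, :, None] / (f * f), r.shape
        ).reshape(n, c, h, w)
        return (np.ascontiguousarray(dx),)

    return _make(np.ascontiguousarray(out), (x,), backward)


def nearest_upsample(x: Tensor, factor: int) -> Tensor:
    """Broadcast each cell to a factor x factor block (adjoint of summation)."""
    n, c, h, w = x.data.shape
    f = factor
    out = np.broadcast_to(
        x.data[:, :, :, None, :, None], (n, c, h, f, w, f)
    ).reshape(n, c, h * f, w * f)

    def backward(g):
        return (g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)),)

    return _make(np.ascontiguousarray(out), (x,), backward)


def local_mean3(x: Tensor) -> Tensor:
    """3x3 box filter with zero padding (the surround of the contrast operator).

    The operator matrix is symmetric, so its adjoint is itself.
    """

    def box(a: np.ndarray) -> np.ndarray:
        ap = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)))
        h, w = a.shape[2], a.shape[3]
        out = np.zeros_like(a)
        for i in range(3):
            for j in range(3):
                out += ap[:, :, i : i + h, j : j + w]
        return out / np.float32(9.0)

    return _make(box(x.data), (x,), lambda g: (box(g),))


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Interpolation matrix for half-pixel-centre bilinear resampling."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[o, lo_c] += 1.0 - frac
        m[o, hi_c] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resampling via fixed interpolation matrices."""
    n, c, h, w = x.data.shape
    my = _bilinear_matrix(out_h, h)
    mx = _bilinear_matrix(out_w, w)
    out = np.einsum("oh,nchw,pw->ncop", my, x.data, mx, optimize=True)

    def backward(g):
        return (np.einsum("oh,ncop,pw->nchw", my, g, mx, optimize=True),)

    return _make(np.ascontiguousarray(out.astype(np.float32)), (x,), backward)


# -- normalization -----------------------------------------------------------

class LayerNorm(Module):
    """Normalization over the last axis (the token-channel axis)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = xhat * g.data + b.data
        d = x.data.shape[-1]

        def backward(go):
            dg = (go * xhat).sum(axis=tuple(range(go.ndim - 1)))
            db = go.sum(axis=tuple(range(go.ndim - 1)))
            gh = go * g.data
            dx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).sum(axis=-1, keepdims=True) / d)
            return dx.astype(np.float32), dg, db

        return _make(out.astype(np.float32), (x, g, b), backward)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), True)
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def __call__(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * self._buffers["running_mean"] + m * mu
            self._buffers["running_var"] = (1 - m) * self._buffers["running_var"] + m * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = xhat * g.data[None, :, None, None] + b.data[None, :, None, None]
        nelem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def backward(go):
            dg = (go * xhat).sum(axis=axes)
            db = go.sum(axis=axes)
            gh = go * g.data[None, :, None, None]
            if training:
                dx = inv[None, :, None, None] * (
                    gh
                    - gh.mean(axis=axes, keepdims=True)
                    - xhat * (gh * xhat).sum(axis=axes, keepdims=True) / nelem
                )
            else:
                dx = gh * inv[None, :, None, None]
            return dx.astype(np.float32), dg, db

        return _make(out.astype(np.float32), (x, g, b), backward)
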