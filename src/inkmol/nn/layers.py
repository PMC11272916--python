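"""Neural-network layers built on the autograd engine.

Provides the pieces the recognizer needs: linear and 2-D convolution
layers, layer normalization, multi-head attention and a pre-norm
transformer decoder block, plus the Adam optimizer. Parameter
initialization is seeded through a numpy Generator passed at construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor, concat


class Module:
    def params(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out


def _init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = _init(rng, (d_in, d_out), d_in)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Conv2d(Module):
    """3x3-style convolution via im2col with a fused custom gradient."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3,
                 stride: int = 1, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.w = _init(rng, (c_out, c_in * kernel * kernel),
                       c_in * kernel * kernel)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        B, C, H, W = x.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        OH = (H + 2 * p - k) // s + 1
        OW = (W + 2 * p - k) // s + 1
        sb, sc, sh, sw = xp.strides
        cols = as_strided(xp, (B, C, k, k, OH, OW),
                          (sb, sc, sh, sw, sh * s, sw * s))
        cols = np.ascontiguousarray(cols).reshape(B, C * k * k, OH * OW)
        out_data = (self.w.data @ cols + self.b.data[:, None]).reshape(
            B, -1, OH, OW)
        weight, bias = self.w, self.b

        def bwd(g):
            gf = g.reshape(B, -1, OH * OW)
            if weight.requires_grad:
                gw = np.einsum("bop,bcp->oc", gf, cols)
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(gf.sum(axis=(0, 2)))
            if x.requires_grad:
                dcols = np.einsum("oc,bop->bcp", weight.data, gf)
                dcols = dcols.reshape(B, C, k, k, OH, OW)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + OH * s:s, j:j + OW * s:s] += \
                            dcols[:, :, i, j]
                x._accum(dxp[:, :, p:p + H, p:p + W])

        return Tensor._node(out_data, (x, weight, bias), bwd)


class MultiHeadAttention(Module):
    """Scaled dot-product attention, optionally causal-masked."""

    def __init__(self, rng, d_model: int, n_heads: int):
        if d_model % n_heads:
            raise ValueError("n_heads must divide d_model")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

    def __call__(self, q_in: Tensor, kv_in: Tensor,
                 causal: bool = False) -> Tensor:
        B, Lq, d = q_in.shape
        Lk = kv_in.shape[1]
        q = self._split(self.wq(q_in), B, Lq)
        k = self._split(self.wk(kv_in), B, Lk)
        v = self._split(self.wv(kv_in), B, Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        if causal:
            bias = np.triu(np.full((Lq, Lk), -1e9, dtype=np.float32), k=1)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, d)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, rng, d_model: int, d_ff: int):
        self.fc1 = Linear(rng, d_model, d_ff)
        self.fc2 = Linear(rng, d_ff, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class DecoderLayer(Module):
    """Pre-norm transformer decoder block: masked self-attention,
    cross-attention to the encoder grid, feed-forward."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        self.self_attn = MultiHeadAttention(rng, d_model, n_heads)
        self.cross_attn = MultiHeadAttention(rng, d_model, n_heads)
        self.ff = FeedForward(rng, d_model, d_ff)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ln3 = LayerNorm(d_model)

    def __call__(self, x: Tensor, memory: Tensor) -> Tensor:
        normed = self.ln1(x)
        x = x + self.self_attn(normed, normed, causal=True)
        x = x + self.cross_attn(self.ln2(x), memory)
        return x + self.ff(self.ln3(x))


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
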