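"""Layers for the scoring network, built on the autodiff core.

Initialization is Glorot-uniform from a caller-supplied generator so model
construction is bit-reproducible from a seed. Arrays are float32 throughout;
gradients are float64 internally.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, constant

DTYPE = np.float32


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    def params(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with a key padding mask."""

    def __init__(self, rng, d_model: int, n_heads: int):
        assert d_model % n_heads == 0
        self.n_heads, self.d_head = n_heads, d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, h, L, dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(dh)  # (B, h, L, L)
        key_mask = pad_mask[:, None, None, :]                 # mask padded keys
        attn = scores.softmax(mask=np.broadcast_to(key_mask, scores.shape))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: attention and feed-forward with residuals."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.ff1 = Linear(rng, d_model, d_ff)
        self.ff2 = Linear(rng, d_ff, d_model)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.norm1(x), pad_mask)
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


class Conv3x3(Module):
    def __init__(self, rng, c_in: int, c_out: int):
        limit = np.sqrt(6.0 / (c_in * 9 + c_out * 9))
        self.w = Tensor(rng.uniform(-limit, limit, size=(c_out, c_in, 3, 3)).astype(DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b)


class UNet(Module):
    """A small U-Net over the pairwise feature grid.

    ``depth`` down/up levels, channel count doubling per level, nearest
    upsampling with skip concatenation, and a 1x1 head to one channel.
    Feature maps are multiplied by the (downsampled) validity mask after
    every convolution so padded grid cells stay exactly zero — this is what
    makes model scores at real positions independent of padding length.
    """

    def __init__(self, rng, c_in: int, base: int, depth: int):
        self.depth = depth
        self.inc = Conv3x3(rng, c_in, base)
        self.down = [Conv3x3(rng, base * 2 ** k, base * 2 ** (k + 1)) for k in range(depth)]
        self.up = [Conv3x3(rng, base * 2 ** (k + 1) + base * 2 ** k, base * 2 ** k)
                   for k in reversed(range(depth))]
        self.head_w = Tensor(_glorot(rng, base, 1), requires_grad=True)
        self.head_b = Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, grid_mask: np.ndarray) -> Tensor:
        masks = [grid_mask.astype(DTYPE)[:, None]]  # (B,1,H,W) per level
        for _ in range(self.depth):
            m = masks[-1]
            B, _, H, W = m.shape
            masks.append(m.reshape(B, 1, H // 2, 2, W // 2, 2).max(axis=(3, 5)))

        # mask the input grid itself: cells (i, j) with exactly one padded
        # index still carry the real position's features in the concat
        h = (self.inc(x * constant(masks[0])) * constant(masks[0])).relu()
        skips = []
        for k, conv in enumerate(self.down):
            skips.append(h)
            h = (conv(h.maxpool2()) * constant(masks[k + 1])).relu()
        for k, conv in enumerate(self.up):
            level = self.depth - 1 - k
            h = concatenate([h.upsample2(), skips[level]], axis=1)
            h = (conv(h) * constant(masks[level])).relu()
        return self._head(h) * constant(masks[0])

    def _head(self, h: Tensor) -> Tensor:
        # 1x1 convolution written as a channel contraction
        B, C, H, W = h.shape
        flat = h.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        out = flat @ self.head_w + self.head_b
        return out.reshape(B, H, W, 1).transpose(0, 3, 1, 2)
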