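"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the backward closure of the
operation that produced it. Calling :meth:`Tensor.backward` on a scalar
result topologically sorts the graph and accumulates gradients into every
tensor created with ``requires_grad=True``. Broadcasting follows numpy
semantics; gradients of broadcast operands are reduced back to the operand
shape. Only the operations the scoring network needs are implemented.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph -------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data, dtype=np.float64)
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data, dtype=np.float64)
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (_as_tensor(other) * (-1.0))

    def __rsub__(self, other):
        return _as_tensor(other) + (self * (-1.0))

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division unsupported; use * t.pow(-1)")
        return self * (1.0 / scalar)

    def __neg__(self):
        return self * (-1.0)

    def pow(self, e: float):
        def bwd(g):
            self._accum(g * e * np.power(self.data, e - 1))

        return Tensor(np.power(self.data, e), _parents=(self,), _backward=bwd)

    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return Tensor(np.matmul(self.data, other.data), _parents=(self, other), _backward=bwd)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        def bwd(g):
            self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def broadcast_to(self, shape):
        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))

        return Tensor(np.broadcast_to(self.data, shape), _parents=(self,), _backward=bwd)

    def __getitem__(self, key):
        def bwd(g):
            full = np.zeros_like(self.data, dtype=np.float64)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor(self.data[key], _parents=(self,), _backward=bwd)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- fused ops ---------------------------------------------------------

    def log_softmax(self, mask: np.ndarray | None = None):
        """Log-softmax over the last axis; positions where ``mask`` is False
        are excluded (their output is a large negative constant and they
        receive no probability mass)."""
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        m = np.max(x, axis=-1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        z = x - m
        with np.errstate(over="ignore"):
            lse = np.log(np.sum(np.exp(z), axis=-1, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)
        if mask is not None:
            out_data = np.where(mask, out_data, -1e30)
            soft = np.where(mask, soft, 0.0)

        def bwd(g):
            if mask is not None:
                g = np.where(mask, g, 0.0)
            self._accum(g - soft * g.sum(axis=-1, keepdims=True))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def softmax(self, mask: np.ndarray | None = None):
        """Softmax over the last axis with optional key mask."""
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        m = np.max(x, axis=-1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(x - m)
        if mask is not None:
            e = np.where(mask, e, 0.0)
        denom = e.sum(axis=-1, keepdims=True)
        denom = np.where(denom == 0.0, 1.0, denom)
        s = e / denom

        def bwd(g):
            self._accum((g - (g * s).sum(axis=-1, keepdims=True)) * s)

        return Tensor(s, _parents=(self,), _backward=bwd)

    # -- convolution family (NCHW) ----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor"):
        """3x3 same-padding convolution. x: (B,C,H,W), weight: (O,C,3,3)."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O = w.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((B, O, H, W), dtype=x.dtype)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, :, di:di + H, dj:dj + W]
                out += np.einsum("bchw,oc->bohw", patch, w[:, :, di, dj], optimize=True)
        out += bias.data[None, :, None, None]

        def bwd(g):
            gxp = np.zeros_like(xp, dtype=np.float64)
            gw = np.zeros_like(w, dtype=np.float64)
            for di in range(3):
                for dj in range(3):
                    patch = xp[:, :, di:di + H, dj:dj + W]
                    gw[:, :, di, dj] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                    gxp[:, :, di:di + H, dj:dj + W] += np.einsum(
                        "bohw,oc->bchw", g, w[:, :, di, dj], optimize=True
                    )
            self._accum(gxp[:, :, 1:1 + H, 1:1 + W])
            weight._accum(gw)
            bias._accum(g.sum(axis=(0, 2, 3)))

        return Tensor(out, _parents=(self, weight, bias), _backward=bwd)

    def maxpool2(self):
        """2x2 max pooling; H and W must be even."""
        B, C, H, W = self.shape
        xr = self.data.reshape(B, C, H // 2, 2, W // 2, 2).swapaxes(3, 4).reshape(
            B, C, H // 2, W // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gr = np.zeros_like(xr, dtype=np.float64)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            self._accum(
                gr.reshape(B, C, H // 2, W // 2, 2, 2).swapaxes(3, 4).reshape(B, C, H, W)
            )

        return Tensor(out, _parents=(self,), _backward=bwd)

    def upsample2(self):
        """Nearest-neighbour 2x upsampling."""
        B, C, H, W = self.shape

        def bwd(g):
            self._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3),
                      _parents=(self,), _backward=bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def constant(x) -> Tensor:
    """A non-trainable tensor."""
    return Tensor(np.asarray(x))


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors), _backward=bwd)
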