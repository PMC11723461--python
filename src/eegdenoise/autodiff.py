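"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine carrying exactly the operations the denoising
network needs: broadcast arithmetic, (batched) matmul, 1-D convolution,
reshape/transpose/concat, reductions, tanh / leaky-ReLU / sigmoid /
softmax.  On top of it sit the layer types (Linear, Conv1d, BatchNorm1d,
multi-head self-attention) and the Adam optimizer.

Network parameters are float32; gradients follow the dtype of the data,
so float64 tensors can be used in finite-difference checks.  All
computation is plain numpy, hence bit-deterministic for a fixed thread
configuration.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "MultiHeadSelfAttention",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (pure inference)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- construction of intermediate nodes --------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # First contribution keeps a reference (no copy); a second
        # contribution allocates, so a shared array is never mutated.
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None if node._parents else node.grad  # free tape grads
        # re-expose gradient on this node if it is a leaf
        # (non-leaf gradients are released above to bound memory)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)),
                                 self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g),
                                 other.data.shape)
                )

        return Tensor._op(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=axis, keepdims=True)
        out_data = z

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._op(out_data, (self,), backward)

    # -- 1-D convolution / pooling -------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """Cross-correlation of (B, Cin, T) with (Cout, Cin, K)."""
        x, w = self.data, weight.data
        B, Cin, T = x.shape
        Cout, Cin2, K = w.shape
        if Cin != Cin2:
            raise ValueError(f"conv1d channel mismatch: {Cin} vs {Cin2}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding))) if padding else x
        Tp = xp.shape[-1]
        Tout = (Tp - K) // stride + 1
        s0, s1, s2 = xp.strides
        cols = as_strided(xp, (B, Cin, K, Tout), (s0, s1, s2, s2 * stride))
        # (B*Tout, Cin*K) @ (Cin*K, Cout)
        cols2 = np.ascontiguousarray(cols.transpose(0, 3, 1, 2)).reshape(
            B * Tout, Cin * K
        )
        out = cols2 @ w.reshape(Cout, Cin * K).T
        out = out.reshape(B, Tout, Cout).transpose(0, 2, 1)
        if bias is not None:
            out = out + bias.data[None, :, None]

        def backward(g):
            # g: (B, Cout, Tout)
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Tout, Cout)
            if weight.requires_grad:
                gw = (g2.T @ cols2).reshape(Cout, Cin, K)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = (g2 @ w.reshape(Cout, Cin * K)).reshape(B, Tout, Cin, K)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, :, k : k + stride * Tout : stride] += gcols[
                        :, :, :, k
                    ].transpose(0, 2, 1)
                self._accum(gxp[:, :, padding : Tp - padding] if padding else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._op(out.astype(x.dtype, copy=False), parents, backward)

    def avg_pool1d(self, k: int = 2):
        """Non-overlapping average pooling over the last axis (T % k == 0)."""
        B, C, T = self.data.shape
        if T % k:
            raise ValueError(f"avg_pool1d: length {T} not divisible by {k}")
        return self.reshape(B, C, T // k, k).mean(axis=3)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._op(np.concatenate(datas, axis=axis), tuple(tensors), backward)


# ===========================================================================
# Layers
# ===========================================================================

class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for mod in (self, *self.modules()):
            for v in mod.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state dict (numpy arrays), for checkpointing ------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and buffer arrays in a stable order."""
        arrays = []
        for mod in (self, *self.modules()):
            for name in sorted(mod.__dict__):
                v = mod.__dict__[name]
                if isinstance(v, Tensor) and v.requires_grad:
                    arrays.append(v.data)
                elif isinstance(v, np.ndarray):
                    arrays.append(v)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for mod in (self, *self.modules()):
            for name in sorted(mod.__dict__):
                v = mod.__dict__[name]
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.array(next(it), dtype=v.data.dtype)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[name] = np.array(next(it), dtype=v.dtype)
        try:
            next(it)
        except StopIteration:
            return
        raise ValueError("state array count mismatch")


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    __call__ = forward


class Conv1d(Module):
    """1-D convolution; ``bias=False`` for layers feeding a BatchNorm
    (the normalization cancels a per-channel bias exactly)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            _kaiming(rng, (out_ch, in_ch, kernel), in_ch * kernel),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)

    __call__ = forward


class BatchNorm1d(Module):
    """Batch normalization over (B, C, T); per-channel statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1).astype(np.float32)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1).astype(np.float32)
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b

    __call__ = forward


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (B, T, C) token sequences."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        H, hd = self.heads, C // self.heads
        qkv = self.qkv(x).reshape(B, T, 3, H, hd).transpose(2, 0, 3, 1, 4)
        q = qkv.reshape(3, B * H, T, hd)
        # split via slicing-by-reshape: take rows 0,1,2 of leading axis
        qd, kd, vd = _split_first(q)
        att = (qd @ kd.transpose(0, 2, 1)) * (1.0 / math.sqrt(hd))
        att = att.softmax(axis=-1)
        y = (att @ vd).reshape(B, H, T, hd).transpose(0, 2, 1, 3).reshape(B, T, C)
        return self.out(y)

    __call__ = forward


def _split_first(t: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split a (3, ...) tensor along the first axis into three views."""

    def make(i: int) -> Tensor:
        def backward(g):
            if t.requires_grad:
                full = np.zeros_like(t.data)
                full[i] = g
                t._accum(full)

        return Tensor._op(t.data[i], (t,), backward)

    return make(0), make(1), make(2)


# ===========================================================================
# Optimizer
# ===========================================================================

class Adam:
    """Adaptive moment estimation with configurable (beta1, beta2)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
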