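"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the tensor, layer and optimiser primitives used by the
liveness-detection networks (:mod:`veinlive.models`, :mod:`veinlive.train`):
dense/grouped/depthwise 2-D convolution, batch and layer normalisation,
multi-head self-attention, SiLU/GELU activations, Adam with a cosine learning
rate schedule, and exact trainable-parameter counting.

The design is deliberately small: a :class:`Tensor` records its parents and a
backward closure; :meth:`Tensor.backward` topologically sorts the graph and
accumulates gradients.  Convolution and pooling are implemented as fused
primitives (im2col/einsum forward, col2im scatter backward); everything else
is composed from elementwise and matmul primitives.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "SiLU",
    "ReLU",
    "GELU",
    "MaxPool2d",
    "Flatten",
    "MultiheadSelfAttention",
    "EncoderLayer",
    "softmax",
    "cross_entropy",
    "global_avg_pool",
    "concat",
    "Adam",
    "cosine_lr",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# Tensor and primitive ops
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and autodiff history."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        for t in topo:
            t.grad = np.zeros_like(t.data) if t.requires_grad else None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a.grad += -g

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g / b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            if a.requires_grad:
                a.grad += g * e * a.data ** (e - 1.0)

        return Tensor._result(a.data ** e, (a,), bw)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a.grad += g * out_data

        return Tensor._result(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a.grad += g / a.data

        return Tensor._result(np.log(a.data), (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            if a.requires_grad:
                a.grad += g * s * (1.0 - s)

        return Tensor._result(s, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a.grad += g * mask

        return Tensor._result(a.data * mask, (a,), bw)

    def silu(self):
        """x * sigmoid(x)."""
        return self * self.sigmoid()

    def gelu(self):
        """Exact GELU, x * Phi(x)."""
        a = self
        phi = 0.5 * (1.0 + _erf(a.data / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * a.data ** 2) / math.sqrt(2.0 * math.pi)

        def bw(g):
            if a.requires_grad:
                a.grad += g * (phi + a.data * pdf)

        return Tensor._result(a.data * phi, (a,), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            if a.requires_grad:
                a.grad += g.reshape(old)

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            if a.requires_grad:
                a.grad += g.transpose(inv)

        return Tensor._result(a.data.transpose(axes), (a,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        shape = a.data.shape

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a.grad += np.broadcast_to(g, shape)
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a.grad += np.broadcast_to(gg, shape)

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return Tensor._result(a.data[idx], (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

        return Tensor._result(a.data @ b.data, (a, b), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    tensors = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross entropy over a batch of integer labels."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = labels.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits.grad += g * p / n

    return Tensor._result(np.float32(loss), (logits,), bw)


# ---------------------------------------------------------------------------
# Convolution / pooling primitives
# ---------------------------------------------------------------------------

def _cols_view(xp: np.ndarray, kh: int, kw: int, stride: int,
               Ho: int, Wo: int) -> np.ndarray:
    B, C = xp.shape[:2]
    sb, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, Ho, Wo), (sb, sc, sh, sw, sh * stride, sw * stride))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    Weight layout is (out_ch, in_ch // groups, kh, kw); `groups == in_ch`
    gives a depthwise convolution.
    """
    B, Ci, H, W = x.data.shape
    Co, Cig, kh, kw = w.data.shape
    if Ci != Cig * groups:
        raise ValueError(f"channel mismatch: input {Ci}, weight expects {Cig * groups}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    cols = _cols_view(xp, kh, kw, s, Ho, Wo)
    G, Og = groups, Co // groups
    colsg = cols.reshape(B, G, Cig, kh, kw, Ho, Wo)
    wg = w.data.reshape(G, Og, Cig, kh, kw)
    out = np.einsum("bgcijhw,gocij->bgohw", colsg, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(B, Co, Ho, Wo))
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g5 = g.reshape(B, G, Og, Ho, Wo)
        if w.requires_grad:
            gw = np.einsum("bgohw,bgcijhw->gocij", g5, colsg, optimize=True)
            w.grad += gw.reshape(Co, Cig, kh, kw)
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            dcols = np.einsum("bgohw,gocij->bgcijhw", g5, wg, optimize=True)
            dcols = dcols.reshape(B, Ci, kh, kw, Ho, Wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
            x.grad += dxp[:, :, p:p + H, p:p + W] if p else dxp

    return Tensor._result(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling on NCHW input; padded positions are -inf."""
    s = stride or kernel
    k, p = int(kernel), int(padding)
    B, C, H, W = x.data.shape
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    cols = _cols_view(xp, k, k, s, Ho, Wo).reshape(B, C, k * k, Ho, Wo)
    am = cols.argmax(axis=2)
    out = np.take_along_axis(cols, am[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        if not x.requires_grad:
            return
        onehot = (np.arange(k * k)[None, None, :, None, None] == am[:, :, None])
        dcols = (onehot * g[:, :, None]).reshape(B, C, k, k, Ho, Wo)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
        x.grad += dxp[:, :, p:p + H, p:p + W] if p else dxp

    return Tensor._result(np.ascontiguousarray(out), (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) spatial mean."""
    return x.mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, _ in list(self.buffers()):
            key = "buffer:" + name
            if key in state:
                obj: Module = self
                *path, attr = name.split(".")
                for part in path:
                    obj = getattr(obj, part) if not part.isdigit() else obj[int(part)]
                getattr(obj, attr)[...] = state[key]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(3.0) * math.sqrt(2.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must be divisible by groups")
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.eps, self.momentum = eps, momentum
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.reshape(c) - self.running_mean)
            self.running_var += m * (var.data.reshape(c) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.weight + self.bias


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (S, N, D) sequences."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        rng = rng or np.random.default_rng()
        self.q = Linear(dim, dim, rng=rng)
        self.k = Linear(dim, dim, rng=rng)
        self.v = Linear(dim, dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.heads = heads
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        S, N, D = x.shape
        h, dh = self.heads, D // self.heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(S, N, h, dh).transpose(0, 2, 1, 3)  # (S, h, N, dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(S, N, D)
        return self.proj(out)


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer (MHSA + MLP, residual both)."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float = 2.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = int(round(dim * mlp_ratio))
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng=rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).gelu())


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation with optional weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int,
              eta_min: float = 1e-6) -> float:
    """Cosine annealing from lr0 to eta_min over `total_epochs` (no restarts)."""
    if total_epochs <= 1:
        return lr0
    frac = epoch / (total_epochs - 1)
    return eta_min + 0.5 * (lr0 - eta_min) * (1.0 + math.cos(math.pi * frac))


def count_parameters(model: Module) -> int:
    """Exact number of trainable scalar parameters in `model`."""
    return int(sum(p.data.size for p in model.parameters()))
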