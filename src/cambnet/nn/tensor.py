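"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
remembers, for every operation, a closure that propagates the output
gradient back to the operation's inputs.  ``backward()`` runs the closures
in reverse topological order.  Convolutions, pooling and batch
normalisation are implemented as fused primitives with hand-written
backward passes (see :mod:`cambnet.nn.layers` for the module wrappers);
everything else is composed from the elementwise/reduction primitives
below.

All floating point work is float32.  Gradients are retained on every node
of the graph, which is what class-activation mapping needs to read the
gradient of a logit with respect to an intermediate feature map.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype.kind == "f" and a.dtype != np.float32:
        a = a.astype(np.float32)
    elif a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node.

        ``grad`` defaults to ones (so scalars seed with 1.0).
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    data = np.empty_like(a.data)
    pos = a.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


# -- shape / reduction ----------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)
    orig = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return _make(data, (a,), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(np.asarray(data, dtype=np.float32), (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(ts, parts):
            if t.requires_grad:
                t._accumulate(part)

    return _make(data, ts, backward)


def matmul(a, b) -> Tensor:
    """2-D matrix product with gradients."""
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


# -- spatial primitives (NCHW) --------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x, w, stride: int = 1, padding: tuple[int, int] | int = 0) -> Tensor:
    """Cross-correlation of ``x`` (N,Ci,H,W) with ``w`` (Co,Ci,kh,kw).

    Implemented as a sum over kernel offsets of channel-mixing products on
    shifted views, which is fast for the small kernels used here and keeps
    the backward pass symmetric.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, ci, h, wd = x.data.shape
    co, ci_w, kh, kw = w.data.shape
    if ci != ci_w:
        raise ValueError(f"conv2d channel mismatch: input {ci}, weight {ci_w}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    s = stride
    xp = _pad_hw(x.data, ph, pw)
    ho = (h + 2 * ph - kh) // s + 1
    wo = (wd + 2 * pw - kw) // s + 1
    acc = np.zeros((co, n, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            # (Co,Ci) x (N,Ci,Ho,Wo) -> (Co,N,Ho,Wo)
            acc += np.tensordot(w.data[:, :, i, j], xs, axes=(1, 1))
    out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))

    def backward(g):
        gt = g.transpose(1, 0, 2, 3)  # (Co,N,Ho,Wo)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                    gw[:, :, i, j] = np.tensordot(gt, xs, axes=([1, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # (Ci,Co) x (Co,N,Ho,Wo) -> (Ci,N,Ho,Wo)
                    t = np.tensordot(w.data[:, :, i, j], gt, axes=(0, 0))
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += t.transpose(
                        1, 0, 2, 3
                    )
            if ph or pw:
                gxp = gxp[:, :, ph : ph + h, pw : pw + wd]
            x._accumulate(gxp)

    return _make(out, (x, w), backward)


def depthwise_conv2d(x, w, stride: int = 1, padding: tuple[int, int] | int = 0) -> Tensor:
    """Per-channel (groups = channels) convolution; ``w`` is (C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    cw, kh, kw = w.data.shape
    if c != cw:
        raise ValueError(f"depthwise_conv2d channel mismatch: input {c}, weight {cw}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    s = stride
    xp = _pad_hw(x.data, ph, pw)
    ho = (h + 2 * ph - kh) // s + 1
    wo = (wd + 2 * pw - kw) // s + 1
    out = np.zeros((n, c, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            out += w.data[None, :, i, j, None, None] * xs

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                    gw[:, i, j] = np.einsum("nchw,nchw->c", g, xs, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += (
                        w.data[None, :, i, j, None, None] * g
                    )
            if ph or pw:
                gxp = gxp[:, :, ph : ph + h, pw : pw + wd]
            x._accumulate(gxp)

    return _make(out, (x, w), backward)


def maxpool2d(x, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel = stride); H, W divisible by kernel."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    k = kernel
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial dims {(h, w)} not divisible by {k}")
    ho, wo = h // k, w // k
    xr = x.data.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(xr).reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = (
            gflat.reshape(n, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    return _make(out, (x,), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) per channel; fused backward.

    ``running_mean``/``running_var`` are plain ndarrays updated in place
    during training.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased running variance, biased batch variance in the transform
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data[None, :, None, None] * invstd[None, :, None, None]
        if training:
            m = n * h * w
            sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = gs * (g - sum_g / m - xhat * sum_gx / m)
        else:
            gx = gs * g
        x._accumulate(gx.astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


# -- losses ----------------------------------------------------------------

def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax of an (N, C) tensor."""
    logits = as_tensor(logits)
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    z = logits - m
    lse = log(sum_(exp(z), axis=1, keepdims=True))
    return z - lse


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (N, C)."""
    labels = np.asarray(labels)
    n, c = as_tensor(logits).shape
    onehot = np.zeros((n, c), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    lp = log_softmax(logits)
    return mul(sum_(mul(lp, Tensor(onehot))), -1.0 / n)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain ndarray softmax used at inference time."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
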