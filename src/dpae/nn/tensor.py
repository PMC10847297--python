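"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the denoising autoencoders in this package:
broadcast-aware elementwise arithmetic, 2-D matmul, concatenation, basic
slicing, reshape, the SeLU/sigmoid/tanh activations, reductions, a fused
batch-normalization op and a fused 1-D convolution op.  Gradient
correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (GRU unrolling)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return index(self, key)

    def reshape(self, *shape):
        return reshape(self, shape)

    def mean(self):
        return mean(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), backward)


def index(a: Tensor, key) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[key]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

    return _node(out_data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _node(out_data, (a,), backward)


def selu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    exp = np.exp(np.minimum(a.data, 0.0))
    out_data = SELU_SCALE * np.where(pos, a.data, SELU_ALPHA * (exp - 1.0))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * SELU_SCALE * np.where(pos, 1.0, SELU_ALPHA * exp))

    return _node(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data**2))

    return _node(out_data, (a,), backward)


def mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.mean(), dtype=a.data.dtype)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, g / a.data.size))

    return _node(out_data, (a,), backward)


def mse(pred: Tensor, target: Tensor) -> Tensor:
    """Mean squared error (mean over all elements)."""
    diff = sub(pred, target)
    return mean(mul(diff, diff))


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over axis 0 (training mode).

    Returns (output tensor, batch mean, batch variance); the statistics are
    plain arrays for the caller's running-average bookkeeping.
    """
    mu = x.data.mean(axis=0)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data
    n = x.data.shape[0]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gsum = g.sum(axis=0)
            gx_hat_sum = (g * xhat).sum(axis=0)
            x._accumulate(gamma.data * inv / n * (n * g - gsum - xhat * gx_hat_sum))

    return _node(out_data, (x, gamma, beta), backward), mu, var


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int, pad: int) -> Tensor:
    """Fused 1-D convolution.

    ``x`` is (batch, c_in, length); ``w`` is (c_out, c_in * kernel);
    ``b`` is (c_out,).  Output is (batch, c_out, l_out) with
    l_out = floor((length + 2·pad − kernel)/stride) + 1.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    batch, c_in, length = x.data.shape
    c_out = w.data.shape[0]
    kernel = w.data.shape[1] // c_in
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    windows = windows[:, :, ::stride, :]  # (batch, c_in, l_out, kernel)
    l_out = windows.shape[2]
    cols = windows.transpose(0, 2, 1, 3).reshape(batch * l_out, c_in * kernel)
    out2 = cols @ w.data.T + b.data
    out_data = out2.reshape(batch, l_out, c_out).transpose(0, 2, 1)

    def backward(g):
        g2 = g.transpose(0, 2, 1).reshape(batch * l_out, c_out)
        if w.requires_grad:
            w._accumulate(g2.T @ cols)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w.data).reshape(batch, l_out, c_in, kernel).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for k in range(kernel):
                dxp[:, :, k : k + stride * l_out : stride] += dcols[:, :, :, k]
            x._accumulate(dxp[:, :, pad : pad + length] if pad else dxp)

    return _node(out_data, (x, w, b), backward)
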