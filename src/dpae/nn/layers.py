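"""Trainable layers built on the Tensor graph.

Initialization is LeCun-normal (std = 1/sqrt(fan_in)), the scheme under
which SeLU activations are self-normalizing; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


def _lecun_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dtype)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


_ACTIVATIONS = {"selu": T.selu, "sigmoid": T.sigmoid, "tanh": T.tanh, None: lambda t: t, "linear": lambda t: t}


class Dense(Layer):
    """Fully connected layer, y = act(x W + b)."""

    def __init__(self, in_features: int, out_features: int, activation: str | None = "selu",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        self.W = Tensor(_lecun_normal(rng, (in_features, out_features), in_features, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return _ACTIVATIONS[self.activation](T.add(T.matmul(x, self.W), self.b))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Per-feature batch normalization with running statistics for inference."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.width = width
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(width, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(width, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(width, dtype=dtype)
        self.running_var = np.ones(width, dtype=dtype)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if training:
            out, mu, var = T.batchnorm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        # inference path: affine transform with frozen statistics
        scale = Tensor(self.gamma.data * inv)
        shift = Tensor(self.beta.data - self.gamma.data * self.running_mean * inv)
        return T.add(T.mul(x, scale), shift)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Conv1d(Layer):
    """1-D convolution over (batch, channels, length) with 'same-ish' padding k//2."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int,
                 activation: str | None = "selu", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.activation = activation
        fan_in = in_channels * kernel
        self.W = Tensor(_lecun_normal(rng, (out_channels, fan_in), fan_in, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.kernel) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        return _ACTIVATIONS[self.activation](T.conv1d(x, self.W, self.b, self.stride, self.pad))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class GRU(Layer):
    """Gated recurrent unit over a sequence of (batch, features) tensors.

    h_t = (1 − z_t)·n_t + z_t·h_{t−1}, with update gate z, reset gate r and
    candidate n = tanh(x W_n + r·(h U_n) + b_n).  Returns the full hidden
    sequence; callers take the last element for a fixed-width encoding.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.hidden = hidden
        self.dtype = dtype

        def w(shape, fan_in):
            return Tensor(_lecun_normal(rng, shape, fan_in, dtype), requires_grad=True)

        self.Wr, self.Wz, self.Wn = (w((in_features, hidden), in_features) for _ in range(3))
        self.Ur, self.Uz, self.Un = (w((hidden, hidden), hidden) for _ in range(3))
        self.br = Tensor(np.zeros(hidden, dtype=dtype), requires_grad=True)
        self.bz = Tensor(np.zeros(hidden, dtype=dtype), requires_grad=True)
        self.bn = Tensor(np.zeros(hidden, dtype=dtype), requires_grad=True)
        self._one = Tensor(np.asarray(1.0, dtype=dtype))

    def __call__(self, seq: list[Tensor]) -> list[Tensor]:
        batch = seq[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.hidden), dtype=self.dtype))
        outputs = []
        for x in seq:
            r = T.sigmoid(T.add(T.add(T.matmul(x, self.Wr), T.matmul(h, self.Ur)), self.br))
            z = T.sigmoid(T.add(T.add(T.matmul(x, self.Wz), T.matmul(h, self.Uz)), self.bz))
            n = T.tanh(T.add(T.add(T.matmul(x, self.Wn), T.mul(r, T.matmul(h, self.Un))), self.bn))
            h = T.add(T.mul(T.sub(self._one, z), n), T.mul(z, h))
            outputs.append(h)
        return outputs

    def parameters(self) -> list[Tensor]:
        return [self.Wr, self.Wz, self.Wn, self.Ur, self.Uz, self.Un, self.br, self.bz, self.bn]
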