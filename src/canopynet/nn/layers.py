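"""Trainable layers built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: a named container of trainable tensors."""

    def params(self) -> list[Tensor]:
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``x @ W + b`` with an optional activation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.w = Tensor(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation

    def __call__(self, x) -> Tensor:
        y = ad.add(ad.matmul(x, self.w), self.b)
        if self.activation == "relu":
            y = ad.relu(y)
        elif self.activation == "tanh":
            y = ad.tanh(y)
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    def params(self):
        return [self.w, self.b]


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep) / keep
        return ad.mul(x, Tensor(mask))


class SimpleRNN(Layer):
    """Vanilla tanh recurrent layer."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.wx = Tensor(glorot_uniform(rng, (in_dim, units), in_dim, units),
                         requires_grad=True)
        self.wh = Tensor(glorot_uniform(rng, (units, units), units, units),
                         requires_grad=True)
        self.b = Tensor(np.zeros(units), requires_grad=True)
        self.return_sequences = return_sequences

    def __call__(self, x) -> Tensor:
        return ad.rnn_forward(x, self.wx, self.wh, self.b, self.return_sequences)

    def params(self):
        return [self.wx, self.wh, self.b]


class LSTM(Layer):
    """LSTM layer; forget-gate bias initialized to 1 (standard practice)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.units = units
        self.wx = Tensor(glorot_uniform(rng, (in_dim, 4 * units), in_dim, units),
                         requires_grad=True)
        self.wh = Tensor(glorot_uniform(rng, (units, 4 * units), units, units),
                         requires_grad=True)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.return_sequences = return_sequences

    def __call__(self, x) -> Tensor:
        return ad.lstm_forward(x, self.wx, self.wh, self.b, self.return_sequences)

    def params(self):
        return [self.wx, self.wh, self.b]


class Conv1D(Layer):
    """1-D convolution over the time axis with 'same' zero padding.

    Input (batch, time, channels) -> output (batch, time, filters).
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        fan_in = in_channels * kernel_size
        self.w = Tensor(glorot_uniform(rng, (kernel_size, in_channels, filters),
                                       fan_in, filters), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)
        self.kernel_size = kernel_size
        self.activation = activation

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        B, T, C = x.data.shape
        pad = self.kernel_size // 2
        zeros = Tensor(np.zeros((B, pad, C)))
        xp = ad.concat([zeros, x, zeros], axis=1)
        terms = [ad.matmul(xp[:, k:k + T, :], self.w[k]) for k in range(self.kernel_size)]
        y = terms[0]
        for t in terms[1:]:
            y = ad.add(y, t)
        y = ad.add(y, self.b)
        if self.activation == "relu":
            y = ad.relu(y)
        return y

    def params(self):
        return [self.w, self.b]
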