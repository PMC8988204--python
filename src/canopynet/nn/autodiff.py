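"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tensor engine: just the operations the network zoo
needs (dense, recurrent, convolutional and attention blocks, MAE losses).
Everything is float64, which keeps training bit-reproducible for a given
seed on one platform and makes gradient checks against central finite
differences tight.

Recurrent layers are provided as *fused* ops (:func:`rnn_forward`,
:func:`lstm_forward`) with hand-written backpropagation-through-time, so an
89-step sequence costs a few NumPy calls per step instead of a long chain
of graph nodes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph.

    Graph edges are only recorded when a node requires gradients, so
    inference-mode forward passes build no graph at all.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        if self.requires_grad:
            self._parents = tuple(_parents)
            self._backward = _backward
        else:
            self._parents = ()
            self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this scalar into every reachable leaf."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


# -- elementwise & linear algebra -------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, g)
        _accum(b, g)

    out._backward = _bw if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    out._backward = _bw if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    """``a @ b`` where ``b`` is a 2-D weight matrix and ``a`` is (..., k)."""
    a, b = as_tensor(a), as_tensor(b)
    if b.data.ndim != 2:
        raise ValueError("matmul: right operand must be 2-D")
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, g @ b.data.T)
        if a.data.ndim == 2:
            _accum(b, a.data.T @ g)
        else:
            axes = tuple(range(a.data.ndim - 1))
            _accum(b, np.tensordot(a.data, g, axes=(axes, axes)))

    out._backward = _bw if out.requires_grad else None
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))

    def _bw(g):
        _accum(a, g * (a.data > 0.0))

    out._backward = _bw if out.requires_grad else None
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    out = Tensor(y, _parents=(a,))

    def _bw(g):
        _accum(a, g * (1.0 - y * y))

    out._backward = _bw if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = expit(a.data)
    out = Tensor(y, _parents=(a,))

    def _bw(g):
        _accum(a, g * y * (1.0 - y))

    out._backward = _bw if out.requires_grad else None
    return out


def absolute(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.abs(a.data), _parents=(a,))

    def _bw(g):
        _accum(a, g * np.sign(a.data))

    out._backward = _bw if out.requires_grad else None
    return out


# -- reductions & shape ops --------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def _bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / count)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), _parents=tuple(ts))
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    out._backward = _bw if out.requires_grad else None
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def _bw(g):
        _accum(a, g.reshape(a.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.transpose(axes), _parents=(a,))
    inv = np.argsort(axes)

    def _bw(g):
        _accum(a, g.transpose(inv))

    out._backward = _bw if out.requires_grad else None
    return out


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data[key], _parents=(a,))

    def _bw(g):
        full = np.zeros_like(a.data)
        full[key] += g
        _accum(a, full)

    out._backward = _bw if out.requires_grad else None
    return out


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused backward)."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(a,))

    def _bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(a, y * (g - dot))

    out._backward = _bw if out.requires_grad else None
    return out


# -- fused recurrent ops -----------------------------------------------------

def rnn_forward(x, wx, wh, b, return_sequences: bool = False) -> Tensor:
    """Vanilla tanh RNN over a (batch, time, features) input.

    ``wx``: (features, units), ``wh``: (units, units), ``b``: (units,).
    Returns the final hidden state (batch, units), or the full hidden
    sequence (batch, time, units) when ``return_sequences`` is set.
    """
    x, wx, wh, b = as_tensor(x), as_tensor(wx), as_tensor(wh), as_tensor(b)
    B, T, D = x.data.shape
    H = wh.data.shape[0]
    xp = (x.data.reshape(B * T, D) @ wx.data).reshape(B, T, H) + b.data
    hs = np.empty((T, B, H))
    h = np.zeros((B, H))
    whd = wh.data
    for t in range(T):
        h = np.tanh(xp[:, t, :] + h @ whd)
        hs[t] = h
    out_data = hs.transpose(1, 0, 2) if return_sequences else hs[-1]
    out = Tensor(out_data, _parents=(x, wx, wh, b))

    def _bw(g):
        da = np.zeros((B, T, H))
        dh_next = np.zeros((B, H))
        dwh = np.zeros_like(whd)
        for t in range(T - 1, -1, -1):
            if return_sequences:
                dh = g[:, t, :] + dh_next
            else:
                dh = (g + dh_next) if t == T - 1 else dh_next
            d = dh * (1.0 - hs[t] * hs[t])
            da[:, t, :] = d
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H))
            dwh += h_prev.T @ d
            dh_next = d @ whd.T
        da2 = da.reshape(B * T, H)
        _accum(x, (da2 @ wx.data.T).reshape(B, T, D))
        _accum(wx, x.data.reshape(B * T, D).T @ da2)
        _accum(wh, dwh)
        _accum(b, da2.sum(axis=0))

    out._backward = _bw if out.requires_grad else None
    return out


def lstm_forward(x, wx, wh, b, return_sequences: bool = False) -> Tensor:
    """LSTM over a (batch, time, features) input with fused BPTT.

    Gate order in the stacked weight matrices is (input, forget, cell,
    output); ``wx``: (features, 4*units), ``wh``: (units, 4*units),
    ``b``: (4*units,).
    """
    x, wx, wh, b = as_tensor(x), as_tensor(wx), as_tensor(wh), as_tensor(b)
    B, T, D = x.data.shape
    H = wh.data.shape[0]
    xp = (x.data.reshape(B * T, D) @ wx.data).reshape(B, T, 4 * H) + b.data
    i_s = np.empty((T, B, H))
    f_s = np.empty((T, B, H))
    g_s = np.empty((T, B, H))
    o_s = np.empty((T, B, H))
    c_s = np.empty((T, B, H))
    tc_s = np.empty((T, B, H))
    h_s = np.empty((T, B, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    whd = wh.data
    for t in range(T):
        a = xp[:, t, :] + h @ whd
        i = expit(a[:, :H])
        f = expit(a[:, H:2 * H])
        gg = np.tanh(a[:, 2 * H:3 * H])
        o = expit(a[:, 3 * H:])
        c = f * c + i * gg
        tc = np.tanh(c)
        h = o * tc
        i_s[t], f_s[t], g_s[t], o_s[t], c_s[t], tc_s[t], h_s[t] = i, f, gg, o, c, tc, h
    out_data = h_s.transpose(1, 0, 2) if return_sequences else h_s[-1]
    out = Tensor(out_data, _parents=(x, wx, wh, b))

    def _bw(g):
        da = np.zeros((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dwh = np.zeros_like(whd)
        for t in range(T - 1, -1, -1):
            if return_sequences:
                dh = g[:, t, :] + dh_next
            else:
                dh = (g + dh_next) if t == T - 1 else dh_next
            i, f, gg, o, tc = i_s[t], f_s[t], g_s[t], o_s[t], tc_s[t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = c_s[t - 1] if t > 0 else np.zeros((B, H))
            d_t = da[:, t, :]
            d_t[:, :H] = dc * gg * i * (1.0 - i)
            d_t[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            d_t[:, 2 * H:3 * H] = dc * i * (1.0 - gg * gg)
            d_t[:, 3 * H:] = do * o * (1.0 - o)
            h_prev = h_s[t - 1] if t > 0 else np.zeros((B, H))
            dwh += h_prev.T @ d_t
            dh_next = d_t @ whd.T
            dc_next = dc * f
        da2 = da.reshape(B * T, 4 * H)
        _accum(x, (da2 @ wx.data.T).reshape(B, T, D))
        _accum(wx, x.data.reshape(B * T, D).T @ da2)
        _accum(wh, dwh)
        _accum(b, da2.sum(axis=0))

    out._backward = _bw if out.requires_grad else None
    return out
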