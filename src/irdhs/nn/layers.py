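"""Minimal numpy neural-network layers with manual backpropagation.

This is the package's own differentiation engine for the sequence models:
every layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the gradient w.r.t. its input while accumulating
parameter gradients).  Input gradients propagate all the way back to the
one-hot sequence, which is what Integrated Gradients requires.

Conventions: sequence tensors are (batch, channels, length); dense tensors
are (batch, features).  All layers are deterministic given their parameters;
``BatchNorm1d`` is the only layer whose forward differs between train and
eval mode.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import numpy as np
from scipy.special import erf


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def __init__(self) -> None:
        self.training = True
        self._params: list[Parameter] = []
        self._children: list["Module"] = []

    # -- registration -----------------------------------------------------
    def add_param(self, data: np.ndarray, name: str = "") -> Parameter:
        p = Parameter(data, name=name)
        self._params.append(p)
        return p

    def add_child(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params
        for child in self._children:
            yield from child.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children:
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        """Make all parameters non-trainable and pin normalisation stats."""
        for p in self.parameters():
            p.trainable = False
        for m in self.walk():
            if isinstance(m, BatchNorm1d):
                m.track_stats = False
        return self

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def walk(self) -> Iterator["Module"]:
        """This module and all descendants, depth-first."""
        yield self
        for child in self._children:
            yield from child.walk()

    # -- state ------------------------------------------------------------
    def buffers(self) -> Iterator[np.ndarray]:
        """Non-learnable state arrays (e.g. batch-norm running statistics)."""
        yield from getattr(self, "_buffers", [])
        for child in self._children:
            yield from child.buffers()

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameters and buffers (for best-epoch restore)."""
        arrays = [p.data for p in self.parameters()] + list(self.buffers())
        return [a.copy() for a in arrays]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        arrays = [p.data for p in self.parameters()] + list(self.buffers())
        state = list(state)
        if len(arrays) != len(state):
            raise ValueError("state snapshot does not match module structure")
        for dst, src in zip(arrays, state):
            dst[...] = src


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = [self.add_child(m) for m in modules]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


class Dense(Module):
    """Affine map on (batch, features); Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = self.add_param(rng.uniform(-limit, limit, (n_in, n_out)), "W")
        self.b = self.add_param(np.zeros(n_out), "b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.data.T


class Conv1d(Module):
    """Stride-1 1-D convolution with optional dilation; He-uniform init.

    padding='same' preserves length; 'valid' yields L - (k-1)*dilation.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        padding: str = "same",
    ):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.dilation = dilation
        self.padding = padding
        fan_in = c_in * kernel
        limit = math.sqrt(6.0 / fan_in)
        self.W = self.add_param(rng.uniform(-limit, limit, (c_out, c_in, kernel)), "W")
        self.b = self.add_param(np.zeros(c_out), "b")

    def _pads(self, length: int) -> tuple[int, int, int]:
        span = (self.kernel - 1) * self.dilation + 1
        if self.padding == "same":
            total = span - 1
            left = total // 2
            return left, total - left, length
        l_out = length - span + 1
        if l_out < 1:
            raise ValueError(f"input length {length} too short for kernel span {span}")
        return 0, 0, l_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        left, right, l_out = self._pads(length)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right))) if left or right else x
        col = np.empty((b, self.c_in, self.kernel, l_out))
        for j in range(self.kernel):
            off = j * self.dilation
            col[:, :, j, :] = xp[:, :, off : off + l_out]
        self._col, self._in_shape, self._pad_lr = col, x.shape, (left, right)
        y = np.einsum("bckl,ock->bol", col, self.W.data, optimize=True)
        return y + self.b.data[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("bckl,bol->ock", self._col, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2))
        dcol = np.einsum("bol,ock->bckl", dout, self.W.data, optimize=True)
        b, c, length = self._in_shape
        left, right = self._pad_lr
        l_out = dout.shape[2]
        dxp = np.zeros((b, c, length + left + right))
        for j in range(self.kernel):
            off = j * self.dilation
            dxp[:, :, off : off + l_out] += dcol[:, :, j, :]
        return dxp[:, :, left : left + length] if (left or right) else dxp


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, length).

    Uses biased batch variance; running statistics updated with momentum for
    eval-mode inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones(channels), "gamma")
        self.beta = self.add_param(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._buffers = [self.running_mean, self.running_var]
        self.momentum = momentum
        self.eps = eps
        self.track_stats = True  # cleared when frozen: always use running stats

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training and self.track_stats:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma.data[None, :, None] * self._xhat + self.beta.data[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None]
        dxhat = dout * g
        if not (self.training and self.track_stats):
            return dxhat / std[None, :, None]
        n = dout.shape[0] * dout.shape[2]
        mean_d = dxhat.mean(axis=(0, 2), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return (dxhat - mean_d - xhat * mean_dx) / std[None, :, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Module):
    """Exact Gaussian-error linear unit: x * Phi(x)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._phi = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._phi

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * self._x**2)
        return dout * (self._phi + self._x * pdf)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                           np.exp(x) / (1.0 + np.exp(x)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class MaxPool1d(Module):
    """Non-overlapping max pooling; requires length divisible by width."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if length % self.width:
            raise ValueError(
                f"length {length} not divisible by pool width {self.width}"
            )
        xr = x.reshape(b, c, length // self.width, self.width)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, length = self._in_shape
        dxr = np.zeros((b, c, length // self.width, self.width))
        bi, ci, wi = np.ix_(np.arange(b), np.arange(c), np.arange(length // self.width))
        dxr[bi, ci, wi, self._argmax] = dout
        return dxr.reshape(b, c, length)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class MeanPool(Module):
    """Mean over positions: (B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class AttentionPool(Module):
    """Attention pooling over positions, as used after conv towers.

    A learned linear map scores each position; a softmax over positions
    yields attention weights; the output is the weight-averaged feature
    vector: (B, C, L) -> (B, C).
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        limit = math.sqrt(6.0 / (channels + 1))
        self.w = self.add_param(rng.uniform(-limit, limit, channels), "w")
        self.b = self.add_param(np.zeros(1), "b")

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        s = np.einsum("bcl,c->bl", x, self.w.data) + self.b.data[0]
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._a = self.attention_weights(x)
        return np.einsum("bcl,bl->bc", x, self._a)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._x, self._a
        dx = np.einsum("bc,bl->bcl", dout, a)
        da = np.einsum("bc,bcl->bl", dout, x)
        ds = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.w.grad += np.einsum("bl,bcl->c", ds, x)
        self.b.grad += ds.sum()
        dx += np.einsum("bl,c->bcl", ds, self.w.data)
        return dx


class DualPath(Module):
    """Sum of a linear and a non-linear branch applied to the same input.

    The linear branch gives every block a direct gradient path from output
    to input, the non-linear branch adds expressiveness — the dual-path
    convolutional block pattern of chromatin-state CNNs.
    """

    def __init__(self, linear: Module, nonlinear: Module):
        super().__init__()
        self.linear = self.add_child(linear)
        self.nonlinear = self.add_child(nonlinear)

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.linear.forward(x)
        b = self.nonlinear.forward(x)
        if a.shape != b.shape:
            raise ValueError("dual-path branches must produce equal shapes")
        return a + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.linear.backward(dout) + self.nonlinear.backward(dout)


class Residual(Module):
    """y = x + f(x); f must preserve shape."""

    def __init__(self, inner: Module):
        super().__init__()
        self.inner = self.add_child(inner)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.inner.forward(x)
        if y.shape != x.shape:
            raise ValueError("residual inner module must preserve shape")
        return x + y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.inner.backward(dout)


class Squeeze(Module):
    """(B, 1) -> (B,)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout[:, None]
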