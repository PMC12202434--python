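"""Minimal numpy neural-network engine for the glucose forecasters.

Layers compute exact analytic gradients (verified against finite differences
in the test suite) and hold their parameters as :class:`Param` objects that
an :class:`Adam` optimizer updates in place.  Only what the forecasting
architectures need is implemented: dense layers, LSTM cells with full
backpropagation through time, 1-D dilated convolutions with same padding,
max-pooling, nearest-neighbour upsampling, dropout and ReLU/tanh
activations.

Everything is float64 and batch-first:

* dense inputs: ``(batch, features)``
* sequence inputs: ``(batch, time, channels)``

Determinism: all initialization and dropout draws come from a
``numpy.random.Generator`` supplied by the caller.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class LSTM(Layer):
    """Single LSTM layer unrolled over the input sequence.

    Gates in i, f, g, o order; forget-gate bias initialized to 1.  Returns
    the full hidden sequence (``return_sequences=True``) or the last hidden
    state.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.units = units
        self.return_sequences = return_sequences
        self.Wx = Param(glorot(rng, (n_in, 4 * units), n_in, units))
        self.Wh = Param(np.concatenate([orthogonal(rng, units) for _ in range(4)], axis=1))
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, U))
        for t in range(T):
            z = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, grad):
        x = self._x
        B, T, D = x.shape
        U = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            if self.return_sequences:
                dh = grad[:, t, :] + dh_next
            else:
                dh = (grad if t == T - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            self.Wx.grad += x[:, t, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv1D(Layer):
    """1-D convolution, same padding, optional dilation."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dilation: int = 1):
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.kernel = kernel
        self.dilation = dilation
        fan_in = c_in * kernel
        self.W = Param(glorot(rng, (kernel, c_in, c_out), fan_in, c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        B, L, C = x.shape
        pad = self.dilation * (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._xp, self._L = xp, L
        y = np.broadcast_to(self.b.value, (B, L, self.W.value.shape[2])).copy()
        for k in range(self.kernel):
            off = k * self.dilation
            y += xp[:, off:off + L, :] @ self.W.value[k]
        return y

    def backward(self, grad):
        xp, L = self._xp, self._L
        pad = self.dilation * (self.kernel - 1) // 2
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            off = k * self.dilation
            self.W.grad[k] += np.tensordot(xp[:, off:off + L, :], grad, axes=([0, 1], [0, 1]))
            dxp[:, off:off + L, :] += grad @ self.W.value[k].T
        self.b.grad += grad.sum(axis=(0, 1))
        return dxp[:, pad:pad + L, :] if pad else dxp


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train=False):
        B, L, C = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        xr = x.reshape(B, L // self.pool, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        B, Lp, C = grad.shape
        dx = np.zeros((B, Lp, self.pool, C))
        bi, li, ci = np.ogrid[:B, :Lp, :C]
        dx[bi, li, self._arg, ci] = grad
        return dx.reshape(self._shape)


class Upsample1D(Layer):
    """Nearest-neighbour upsampling along time."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, train=False):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad):
        B, L, C = grad.shape
        return grad.reshape(B, L // self.factor, self.factor, C).sum(axis=2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def n_parameters(params: list[Param]) -> int:
    return int(sum(p.value.size for p in params))
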