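"""Minimal NumPy backend for the 1D convolutional classifier.

Implements exactly the layer set the architecture needs - 1D convolution with
'same' padding, batch normalization, ReLU, dropout, max-pooling, dense layers -
together with Glorot-uniform initialization, the Adam optimizer, and a fused
sigmoid + binary-cross-entropy output for numerically stable gradients.
Shapes follow the channels-last convention: activations are (batch, length,
channels) until flattened.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Network", "Adam", "build_layers", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Stride-1 'same'-padded 1D convolution, channels last."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        W = _glorot_uniform(rng, (kernel * c_in, c_out), kernel * c_in, kernel * c_out)
        b = np.zeros(c_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, training):
        B, L, C = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (B, L, C, k) -> (B, L, k, C) -> (B*L, k*C)
        cols = sliding_window_view(xp, self.k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(B * L, self.k * C)
        self._shape = (B, L, C)
        out = self._cols @ self.params[0] + self.params[1]
        return out.reshape(B, L, self.c_out)

    def backward(self, dout):
        B, L, C = self._shape
        pad = self.k // 2
        dflat = dout.reshape(B * L, self.c_out)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params[0].T).reshape(B, L, self.k, C)
        dxp = np.zeros((B, L + 2 * pad, C))
        for j in range(self.k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, pad : pad + L, :]


class BatchNorm(Layer):
    """Per-channel normalization over batch (and length) axes."""

    def __init__(self, channels, momentum=0.9, eps=1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        gamma, beta = np.ones(channels), np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, axes, x.size // x.shape[-1])
        return self.params[0] * xhat + self.params[1]

    def backward(self, dout):
        xhat, inv_std, axes, m = self._cache
        self.grads[0][...] = (dout * xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.params[0]
        return (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training):
        B, L, C = x.shape
        L2 = L // self.pool
        v = x[:, : L2 * self.pool, :].reshape(B, L2, self.pool, C)
        self._arg = v.argmax(axis=2)
        self._shape = (B, L, C)
        return v.max(axis=2)

    def backward(self, dout):
        B, L, C = self._shape
        L2 = L // self.pool
        dx = np.zeros((B, L2, self.pool, C))
        b, l, c = np.ogrid[:B, :L2, :C]
        dx[b, l, self._arg, c] = dout
        return np.concatenate(
            [dx.reshape(B, L2 * self.pool, C), np.zeros((B, L - L2 * self.pool, C))],
            axis=1,
        )


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        W = _glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        b = np.zeros(n_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Network:
    """A plain layer stack ending in a single logit."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self):
        extra = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                extra.extend([layer.running_mean, layer.running_var])
        return [p.copy() for p in self.params] + [e.copy() for e in extra]

    def set_weights(self, weights):
        n = len(self.params)
        for p, w in zip(self.params, weights[:n]):
            p[...] = w
        extra = iter(weights[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()


class Adam:
    """Adaptive Moment Estimation over a parameter list."""

    def __init__(self, params, lr=1e-3, beta_1=0.9, beta_2=0.999, epsilon=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta_1, beta_2, epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def build_layers(
    n_features: int,
    n_filters=(256, 128, 64, 32),
    kernel_size: int = 3,
    dropout_rate: float = 0.2,
    pool_size: int = 2,
    dense_units: int = 8,
    rng: np.random.Generator | None = None,
    dropout_rng: np.random.Generator | None = None,
) -> Network:
    """Assemble the conv->BN stack with dropout, pooling and dense head."""
    rng = rng or np.random.default_rng()
    dropout_rng = dropout_rng or np.random.default_rng()
    layers: list[Layer] = []
    c_in = 1
    for c_out in n_filters:
        layers.append(Conv1D(c_in, c_out, kernel_size, rng))
        layers.append(ReLU())
        layers.append(BatchNorm(c_out))
        c_in = c_out
    layers.append(Dropout(dropout_rate, dropout_rng))
    layers.append(MaxPool1D(pool_size))
    layers.append(Flatten())
    flat = (n_features // pool_size) * c_in
    layers.append(Dense(flat, dense_units, rng))
    layers.append(ReLU())
    layers.append(Dense(dense_units, 1, rng))
    return Network(layers)
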