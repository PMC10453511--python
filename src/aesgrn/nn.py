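"""Minimal feed-forward / convolutional / recurrent regression networks.

Plain-numpy layers with explicit backprop, minibatch Adam, and MSE loss.
Scope is deliberately narrow: the per-gene forecasters are tiny (tens of
units, tens to hundreds of samples), so a hand-rolled backend with
deterministic seeding is both fast enough and bit-reproducible, which the
closed-loop simulator requires.  Gradients of every layer are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import NumericError, SpecError

__all__ = [
    "Dense",
    "Activation",
    "Dropout",
    "Reshape",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "LSTM",
    "Network",
    "Adam",
    "train_network",
]

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z, a: a * (1.0 - a),
    ),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class Layer:
    """Base layer: parameters and gradients are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.params[0].T


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        if name not in _ACTIVATIONS:
            raise SpecError(f"unknown activation {name!r}")
        self.name = name
        self._f, self._df = _ACTIVATIONS[name]

    def forward(self, x, train):
        self._z = x
        self._a = self._f(x)
        return self._a

    def backward(self, g):
        return g * self._df(self._z, self._a)


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise SpecError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Reshape(Layer):
    """Gene-major flat vector (n*m) -> sequence (m timesteps, n channels)."""

    def __init__(self, n_genes: int, window: int):
        super().__init__()
        self.n = n_genes
        self.m = window

    def forward(self, x, train):
        return x.reshape(-1, self.n, self.m).transpose(0, 2, 1)

    def backward(self, g):
        return g.transpose(0, 2, 1).reshape(-1, self.n * self.m)


class Conv1D(Layer):
    """1-D convolution over (batch, T, C) -> (batch, T_out, F).

    ``padding="same"`` right-pads with zeros so T_out == T (keeps the
    layer arithmetic T -> T -> T//2 after pooling); ``"valid"`` gives
    T_out == T - k + 1.
    """

    def __init__(self, n_channels: int, n_filters: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same"):
        super().__init__()
        if padding not in ("same", "valid"):
            raise SpecError(f"unknown padding {padding!r}")
        self.k = kernel
        self.padding = padding
        limit = np.sqrt(6.0 / (kernel * n_channels + n_filters))
        w = rng.uniform(-limit, limit, size=(kernel, n_channels, n_filters))
        b = np.zeros(n_filters)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._t_in = x.shape[1]
        if self.padding == "same":
            pad = np.zeros((x.shape[0], self.k - 1, x.shape[2]))
            x = np.concatenate([x, pad], axis=1)
        self._x = x
        t_out = x.shape[1] - self.k + 1
        out = np.tile(self.params[1], (x.shape[0], t_out, 1))
        for k in range(self.k):
            out += x[:, k : k + t_out, :] @ self.params[0][k]
        return out

    def backward(self, g):
        x = self._x
        t_out = g.shape[1]
        dx = np.zeros_like(x)
        self.grads[1][...] = g.sum(axis=(0, 1))
        for k in range(self.k):
            self.grads[0][k][...] = np.einsum("btc,btf->cf", x[:, k : k + t_out, :], g)
            dx[:, k : k + t_out, :] += g @ self.params[0][k].T
        return dx[:, : self._t_in, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the time axis (trailing remainder dropped)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.p = pool

    def forward(self, x, train):
        b, t, c = x.shape
        t_out = t // self.p
        xr = x[:, : t_out * self.p, :].reshape(b, t_out, self.p, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, g):
        b, t_out, c = g.shape
        dx = np.zeros(self._in_shape)
        bi, ti, ci = np.meshgrid(
            np.arange(b), np.arange(t_out), np.arange(c), indexing="ij"
        )
        dx[bi, ti * self.p + self._arg, ci] = g
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM layer over (batch, T, C); emits the final hidden state."""

    def __init__(self, n_channels: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.u = units
        limit = np.sqrt(6.0 / (n_channels + units))
        wx = rng.uniform(-limit, limit, size=(n_channels, 4 * units))
        wh = rng.uniform(-limit, limit, size=(units, 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [wx, wh, b]
        self.grads = [np.zeros_like(wx), np.zeros_like(wh), np.zeros_like(b)]

    def forward(self, x, train):
        wx, wh, b = self.params
        batch, t_len, _ = x.shape
        u = self.u
        h = np.zeros((batch, u))
        c = np.zeros((batch, u))
        self._x = x
        self._cache = []
        for t in range(t_len):
            z = x[:, t, :] @ wx + h @ wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h

    def backward(self, grad_h):
        wx, wh, b = self.params
        x = self._x
        batch, t_len, _ = x.shape
        u = self.u
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(x)
        dh = grad_h
        dc = np.zeros((batch, u))
        for t in range(t_len - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += x[:, t, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = dz @ wx.T
            dh = dz @ wh.T
            dc = dc * f
        return dx


class Network:
    """A sequential stack mapping a batch of inputs to one scalar each."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target.reshape(pred.shape)
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    learning_rate: float,
    max_epochs: int = 200,
    patience: int = 10,
    batch_size: int = 16,
    seed: int = 0,
) -> tuple[float, float]:
    """Minibatch Adam with early stopping on validation MSE.

    One epoch is a full seeded-shuffle pass over the training rows in
    batches of ``batch_size``.  Restores the best-validation weights before
    returning ``(train_mse, val_mse)`` at that point.  Raises
    :class:`NumericError` on a non-finite loss.
    """
    opt = Adam(net.parameters(), lr=learning_rate)
    rng = np.random.default_rng(seed)
    n_rows = x_train.shape[0]
    best_val = np.inf
    best_train = np.inf
    best_weights = net.get_weights()
    stale = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n_rows)
        for lo in range(0, n_rows, batch_size):
            idx = order[lo : lo + batch_size]
            pred = net.forward(x_train[idx], train=True)
            loss, grad = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise NumericError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step(net.gradients())
        val_pred = net.forward(x_val, train=False)
        val_loss = float(np.mean((val_pred.ravel() - y_val.ravel()) ** 2))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            tr_pred = net.forward(x_train, train=False)
            best_train = float(np.mean((tr_pred.ravel() - y_train.ravel()) ** 2))
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    net.set_weights(best_weights)
    return best_train, best_val
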