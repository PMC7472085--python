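"""Minimal numpy neural-network core.

Implements exactly the layer set the two classifier architectures need —
"same"-padded 2-D/1-D convolution, batch normalization, ReLU, max pooling
(2×2/stride-2 with ceil-mode padding, and size-2/stride-1), flatten, LSTM,
dense, dropout — together with Adam and softmax cross-entropy. Every layer has
an analytic backward pass; correctness is pinned by finite-difference gradient
tests. Data layout is channels-last: images are (N, H, W, C), sequences
(N, L, C), LSTM inputs (N, T, features).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "Conv2D", "Conv1D", "BatchNorm", "ReLU",
    "MaxPool2D", "MaxPool1D", "Flatten", "ToSequence", "LSTM", "Dropout",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, v: np.ndarray):
        self.v = np.asarray(v, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    @property
    def size(self) -> int:
        return self.v.size


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    name = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, g):
        self.W.g += self._x.T @ g
        self.b.g += g.sum(axis=0)
        return g @ self.W.v.T


class Conv2D(Layer):
    """3×3 (configurable) same-padded, stride-1 2-D convolution, NHWC.

    Computed as k·k shifted channel-mixing GEMMs rather than im2col, which
    avoids materializing patch matrices (the kernels here are tiny relative
    to the activations).
    """

    def __init__(self, c_in: int, filters: int, k: int = 3, *,
                 rng: np.random.Generator, name: str = "conv2d"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k, self.c_in, self.filters = k, c_in, filters
        fan_in, fan_out = k * k * c_in, k * k * filters
        self.W = Param(_glorot(rng, (k, k, c_in, filters), fan_in, fan_out))
        self.b = Param(np.zeros(filters))
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        W = self.W.v.astype(x.dtype, copy=False)
        self._xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        y = np.zeros((n, h, w, self.filters), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                y += self._xp[:, u : u + h, v : v + w, :] @ W[u, v]
        y += self.b.v.astype(x.dtype, copy=False)
        self._hw = (h, w)
        return y

    def backward(self, g):
        h, w = self._hw
        k, p = self.k, self.k // 2
        flat_g = g.reshape(-1, self.filters)
        for u in range(k):
            for v in range(k):
                patch = self._xp[:, u : u + h, v : v + w, :].reshape(-1, self.c_in)
                self.W.g[u, v] += patch.T @ flat_g
        self.b.g += flat_g.sum(axis=0)
        W = self.W.v.astype(g.dtype, copy=False)
        dxp = np.zeros_like(self._xp)
        for u in range(k):
            for v in range(k):
                dxp[:, u : u + h, v : v + w, :] += g @ W[u, v].T
        return dxp[:, p : p + h, p : p + w, :]


class Conv1D(Layer):
    """3-tap (configurable) same-padded, stride-1 1-D convolution, (N, L, C)."""

    def __init__(self, c_in: int, filters: int, k: int = 3, *,
                 rng: np.random.Generator, name: str = "conv1d"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k, self.c_in, self.filters = k, c_in, filters
        self.W = Param(_glorot(rng, (k, c_in, filters), k * c_in, k * filters))
        self.b = Param(np.zeros(filters))
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, length, _ = x.shape
        k, p = self.k, self.k // 2
        W = self.W.v.astype(x.dtype, copy=False)
        self._xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        y = np.zeros((n, length, self.filters), dtype=x.dtype)
        for u in range(k):
            y += self._xp[:, u : u + length, :] @ W[u]
        y += self.b.v.astype(x.dtype, copy=False)
        self._len = length
        return y

    def backward(self, g):
        length = self._len
        k, p = self.k, self.k // 2
        flat_g = g.reshape(-1, self.filters)
        for u in range(k):
            patch = self._xp[:, u : u + length, :].reshape(-1, self.c_in)
            self.W.g[u] += patch.T @ flat_g
        self.b.g += flat_g.sum(axis=0)
        W = self.W.v.astype(g.dtype, copy=False)
        dxp = np.zeros_like(self._xp)
        for u in range(k):
            dxp[:, u : u + length, :] += g @ W[u].T
        return dxp[:, p : p + length, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes (channels-last)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "batchnorm"):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.name = name

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._ivar
        self._m = x.size // x.shape[-1]
        self._train = train
        return self.gamma.v * self._xhat + self.beta.v

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.gamma.g += (g * self._xhat).sum(axis=axes)
        self.beta.g += g.sum(axis=axes)
        dxhat = g * self.gamma.v
        if not self._train:
            return dxhat * self._ivar
        m = self._m
        return (self._ivar / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2D(Layer):
    """2×2 pool, stride 2, ceil-mode (zero-style) padding: 81→41, 128→64."""

    def __init__(self, name: str = "maxpool2d"):
        self.name = name

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ph, pw = h % 2, w % 2
        self._shape = x.shape
        self._pad = (ph, pw)
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        h2, w2 = xp.shape[1] // 2, xp.shape[2] // 2
        x6 = xp.reshape(n, h2, 2, w2, 2, c)
        out = x6.max(axis=(2, 4))
        mask = x6 == out[:, :, None, :, None, :]
        self._mask = (mask / mask.sum(axis=(2, 4), keepdims=True)).astype(x.dtype)
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        ph, pw = self._pad
        dx6 = self._mask * g[:, :, None, :, None, :]
        dxp = dx6.reshape(n, h + ph, w + pw, c)
        return dxp[:, :h, :w, :]


class MaxPool1D(Layer):
    """Size-2, stride-1, same-length pooling: out[t] = max(x[t], x[t+1])."""

    def __init__(self, name: str = "maxpool1d"):
        self.name = name

    def forward(self, x, train=False):
        shifted = np.concatenate(
            [x[:, 1:], np.full_like(x[:, :1], -np.inf)], axis=1
        )
        self._m = x >= shifted
        return np.where(self._m, x, shifted)

    def backward(self, g):
        dx = np.where(self._m, g, 0.0)
        dx[:, 1:] += np.where(self._m, 0.0, g)[:, :-1]
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class ToSequence(Layer):
    """Present a flat feature vector as a length-1 sequence for the LSTM."""

    def __init__(self, name: str = "to_sequence"):
        self.name = name

    def forward(self, x, train=False):
        return x[:, None, :]

    def backward(self, g):
        return g[:, 0, :]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """LSTM over (N, T, I), returning the last hidden state (N, H).

    Gate order [input, forget, cell-candidate, output]; sigmoid gate
    activations, tanh state activation. Weights: input 4H×I, recurrent 4H×H,
    bias 4H. With length-1 sequences the recurrent weights receive zero
    gradient but are counted as learnables.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str = "lstm"):
        self.n_in, self.hidden = n_in, hidden
        self.Wx = Param(_glorot(rng, (4 * hidden, n_in), n_in, hidden))
        self.Wr = Param(_glorot(rng, (4 * hidden, hidden), hidden, hidden))
        self.b = Param(np.zeros(4 * hidden))
        self.name = name

    def params(self):
        return [self.Wx, self.Wr, self.b]

    def forward(self, x, train=False):
        if x.ndim == 2:
            x = x[:, None, :]
        n, T, _ = x.shape
        H = self.hidden
        h = np.zeros((n, H), dtype=x.dtype)
        c = np.zeros((n, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        Wx = self.Wx.v.astype(x.dtype, copy=False)
        Wr = self.Wr.v.astype(x.dtype, copy=False)
        b = self.b.v.astype(x.dtype, copy=False)
        for t in range(T):
            z = x[:, t] @ Wx.T + h @ Wr.T + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return h

    def backward(self, grad_h):
        x = self._x
        n, T, _ = x.shape
        H = self.hidden
        dh = grad_h
        dc = np.zeros((n, H), dtype=x.dtype)
        dx = np.zeros_like(x)
        Wx = self.Wx.v.astype(x.dtype, copy=False)
        Wr = self.Wr.v.astype(x.dtype, copy=False)
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.g += dz.T @ x[:, t]
            self.Wr.g += dz.T @ h_prev
            self.b.g += dz.sum(axis=0)
            dx[:, t] = dz @ Wx
            dh = dz @ Wr
            dc = dc * f
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout"):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.name = name

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (
            (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        ).astype(x.dtype)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def astype(self, dtype) -> "Sequential":
        """Cast all parameters (and normalization statistics) to ``dtype``."""
        for lay in self.layers:
            for p in lay.params():
                p.v = p.v.astype(dtype)
                p.g = p.g.astype(dtype)
            if isinstance(lay, BatchNorm):
                lay.run_mean = lay.run_mean.astype(dtype)
                lay.run_var = lay.run_var.astype(dtype)
        return self

    def activations(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Layer-name → activation for one inference forward pass."""
        out = {}
        for lay in self.layers:
            x = lay.forward(x, train=False)
            out[lay.name] = x
        return out


class Adam:
    """Adam with the conventional β₁=0.9 and configurable β₂ (default 0.99)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, s in zip(self.params, self.m, self.s):
            m *= b1
            m += (1 - b1) * p.g
            s *= b2
            s += (1 - b2) * p.g**2
            mhat = m / (1 - b1**self.t)
            shat = s / (1 - b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n
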