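"""Minimal numpy neural-network engine.

Forward/backward layers (conv2d via im2col, batch norm, ReLU, 2×2 max
pool, flatten, a single-step LSTM, dense) plus softmax cross-entropy and
Adam.  Everything is deterministic given the rng passed at construction;
arrays are channel-last ``(N, H, W, C)`` for images and ``(N, D)`` for
vectors.  Written for clarity at the small problem sizes this package
trains (tens of images); no attempt at large-scale performance.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: ``params()`` yields (array, grad) pairs for the optimizer."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class SequenceFolding(Layer):
    """Reshapes per-timestep images into a batch for convolution.

    With length-1 sequences (one image per sample) this is the identity;
    it still validates that its input is a 4-D image batch.
    """

    def forward(self, x, train):
        if x.ndim != 4:
            raise ValueError(f"sequence_folding expects (N, H, W, C), got {x.shape}")
        return x

    def backward(self, dout):
        return dout


class SequenceUnfolding(Layer):
    """Inverse of :class:`SequenceFolding`; identity for length-1 sequences."""

    def forward(self, x, train):
        return x

    def backward(self, dout):
        return dout


class Conv2D(Layer):
    """Stride-1 2-D convolution with symmetric zero padding."""

    def __init__(self, fh: int, fw: int, c_in: int, c_out: int, padding: int, rng: np.random.Generator):
        self.fh, self.fw, self.c_in, self.c_out, self.padding = fh, fw, c_in, c_out, padding
        fan_in = fh * fw * c_in
        self.w = _glorot(rng, (fh, fw, c_in, c_out), fan_in, c_out)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train):
        if x.shape[3] != self.c_in:
            raise ValueError(f"conv expects {self.c_in} channels, got {x.shape[3]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, OH, OW, C, FH, FW) -> (N*OH*OW, FH*FW*C)
        win = sliding_window_view(xp, (self.fh, self.fw), axis=(1, 2))
        n, oh, ow = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, -1)
        wf = self.w.reshape(-1, self.c_out)
        out = cols @ wf + self.b
        self._cache = (cols, x.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, self.c_out)

    def backward(self, dout):
        cols, x_shape, (n, oh, ow) = self._cache
        dflat = dout.reshape(n * oh * ow, self.c_out)
        wf = self.w.reshape(-1, self.c_out)
        self.dw[...] = (cols.T @ dflat).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ wf.T).reshape(n, oh, ow, self.fh, self.fw, self.c_in)
        p = self.padding
        dxp = np.zeros((n, x_shape[1] + 2 * p, x_shape[2] + 2 * p, self.c_in))
        for i in range(self.fh):
            for j in range(self.fw):
                dxp[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + x_shape[1], p : p + x_shape[2], :]


class BatchNorm(Layer):
    """Per-channel batch normalization (channel-last); eps 1e-5.

    Inference statistics are the cumulative average of all batch
    statistics seen during training rather than an exponential moving
    average: with the few, large batches this package trains on, an EMA
    from a cold start never converges within the epoch budget and skews
    eval-mode outputs.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._n_batches = 0

    def reset_running(self) -> None:
        """Drop accumulated statistics (used to recalibrate after training)."""
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)
        self._n_batches = 0

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            k = self._n_batches
            self.running_mean = (k * self.running_mean + mean) / (k + 1)
            self.running_var = (k * self.running_var + var) / (k + 1) if k else var
            self._n_batches = k + 1
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.size // x.shape[-1])
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std, axes, m = self._cache
        self.dgamma[...] = np.sum(dout * xhat, axis=axes)
        self.dbeta[...] = np.sum(dout, axis=axes)
        return (self.gamma * inv_std / m) * (m * dout - self.dbeta - xhat * self.dgamma)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool(Layer):
    """Square max pooling with stride equal to the pool size."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train):
        n, h, w, c = x.shape
        p = self.pool
        if h % p or w % p:
            raise ValueError(f"input {h}×{w} not divisible by pool {p}")
        oh, ow = h // p, w // p
        xr = x.reshape(n, oh, p, ow, p, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, p * p)
        self._argmax = xr.argmax(axis=4)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._argmax[..., None], axis=4)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._shape
        p = self.pool
        oh, ow = h // p, w // p
        d = np.zeros((n, oh, ow, c, p * p))
        np.put_along_axis(d, self._argmax[..., None], dout[..., None], axis=4)
        return d.reshape(n, oh, ow, c, p, p).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class LSTMLayer(Layer):
    """Single-step LSTM over length-1 sequences starting from zero state.

    Gate blocks are stacked row-wise in the order (input i, candidate g,
    forget f, output o): the stacked input matrix is ``4·hidden × d`` and
    the stacked recurrent matrix ``4·hidden × hidden``.  With a zero
    initial state the recurrent matrix and the forget gate receive no
    gradient, but both are kept so the parameter shapes match the
    canonical architecture table.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim, self.hidden = input_dim, hidden
        self.wx = _glorot(rng, (4 * hidden, input_dim), input_dim, hidden)
        self.wh = _glorot(rng, (4 * hidden, hidden), hidden, hidden)
        self.b = np.zeros(4 * hidden)
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.wx, self.dwx), (self.wh, self.dwh), (self.b, self.db)]

    def forward(self, x, train):
        if x.shape[1] != self.input_dim:
            raise ValueError(f"lstm expects input dim {self.input_dim}, got {x.shape[1]}")
        h = self.hidden
        z = x @ self.wx.T + self.b  # zero initial hidden state
        i = sigmoid(z[:, :h])
        g = np.tanh(z[:, h : 2 * h])
        o = sigmoid(z[:, 3 * h :])
        c = i * g  # forget term vanishes: zero initial cell state
        tc = np.tanh(c)
        self._cache = (x, i, g, o, tc)
        return o * tc

    def backward(self, dout):
        x, i, g, o, tc = self._cache
        h = self.hidden
        do = dout * tc
        dc = dout * o * (1 - tc**2)
        dz = np.zeros((x.shape[0], 4 * h))
        dz[:, :h] = dc * g * i * (1 - i)
        dz[:, h : 2 * h] = dc * i * (1 - g**2)
        # forget-gate rows stay zero (no cell history at t=0)
        dz[:, 3 * h :] = do * o * (1 - o)
        self.dwx[...] = dz.T @ x
        self.dwh[...] = 0.0
        self.db[...] = dz.sum(axis=0)
        return dz @ self.wx


class Dense(Layer):
    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.w = _glorot(rng, (output_dim, input_dim), input_dim, output_dim)
        self.b = np.zeros(output_dim)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=1)))


class Adam:
    """Adaptive-moment optimizer (beta1 0.9, beta2 0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(params):
            m = self._m.setdefault(k, np.zeros_like(p))
            v = self._v.setdefault(k, np.zeros_like(p))
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
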