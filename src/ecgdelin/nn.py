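"""Sequence-labeling network primitives in plain numpy.

Implements exactly what the delineator architecture needs, with explicit
backpropagation so training has no framework dependency:

* :class:`Conv1D` — 1-D convolution, stride 1, zero-padded to preserve the
  sequence length, ReLU activation.  For filter i at position j the
  activation is phi(b_i + sum_k w_ik x_{j+k-1}).
* :class:`BiLSTM` — standard LSTM cell per direction: input, forget and
  output gates through the logistic function, tanh candidate, cell state
  c_t = f_t*c_{t-1} + i_t*g_t, hidden h_t = o_t*tanh(c_t), with h_0 = c_0 = 0.
  The two directions' hidden sequences are concatenated per timestep, so a
  layer with H units per direction outputs width 2H.
* :class:`TimeDistributedDense` — per-timestep affine map (the class head).
* :func:`softmax` / :func:`softmax_cross_entropy` — the output activation
  and the categorical cross-entropy loss with its gradient.
* :class:`Adam` — adaptive-moment optimizer.

All layers consume/produce arrays of shape (batch, length, channels).
Weights are Glorot-uniform initialized from a caller-supplied seeded
generator; the LSTM forget-gate bias starts at 1.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D:
    """Same-length 1-D convolution with ReLU, kernel ``k``, stride 1."""

    def __init__(self, in_channels: int, filters: int, kernel: int = 3, *,
                 rng: np.random.Generator, activation: str = "relu"):
        if filters < 1 or in_channels < 1 or kernel < 1:
            raise ValidationError("conv dimensions must be positive")
        self.kernel = kernel
        self.activation = activation
        fan_in = kernel * in_channels
        self.W = _glorot(rng, fan_in, filters, (kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def out_channels(self) -> int:
        return self.W.shape[2]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        left = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
        y = self.b + np.zeros((B, L, self.out_channels))
        for j in range(k):
            y += xp[:, j:j + L, :] @ self.W[j]
        self._x_padded, self._pre = xp, y
        return np.maximum(y, 0.0) if self.activation == "relu" else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, pre = self._x_padded, self._pre
        if self.activation == "relu":
            dy = dy * (pre > 0)
        B, Lp, C = xp.shape
        L = dy.shape[1]
        k = self.kernel
        self.dW[...] = 0.0
        self.db[...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(k):
            self.dW[j] = np.tensordot(xp[:, j:j + L, :], dy, axes=([0, 1], [0, 1]))
            dxp[:, j:j + L, :] += dy @ self.W[j].T
        left = (k - 1) // 2
        return dxp[:, left:left + L, :]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One direction of an LSTM layer (standard cell, gate order i,f,g,o)."""

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator):
        H = units
        self.units = H
        self.Wx = _glorot(rng, in_channels, 4 * H, (in_channels, 4 * H))
        self.Wh = _glorot(rng, H, 4 * H, (H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        H = self.units
        i = np.empty((B, L, H)); f = np.empty((B, L, H))
        g = np.empty((B, L, H)); o = np.empty((B, L, H))
        c = np.empty((B, L, H)); tc = np.empty((B, L, H))
        h = np.empty((B, L, H))
        xW = x @ self.Wx + self.b  # precompute the input contribution
        h_prev = np.zeros((B, H))
        c_prev = np.zeros((B, H))
        for t in range(L):
            z = xW[:, t, :] + h_prev @ self.Wh
            i[:, t] = _sigmoid(z[:, :H])
            f[:, t] = _sigmoid(z[:, H:2 * H])
            g[:, t] = np.tanh(z[:, 2 * H:3 * H])
            o[:, t] = _sigmoid(z[:, 3 * H:])
            c_prev = f[:, t] * c_prev + i[:, t] * g[:, t]
            c[:, t] = c_prev
            tc[:, t] = np.tanh(c_prev)
            h_prev = o[:, t] * tc[:, t]
            h[:, t] = h_prev
        self._cache = (x, i, f, g, o, c, tc, h)
        return h

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, i, f, g, o, c, tc, h = self._cache
        B, L, H = dh_out.shape
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dz_all = np.empty((B, L, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            dh = dh_out[:, t] + dh_next
            dc = dc_next + dh * o[:, t] * (1.0 - tc[:, t] ** 2)
            c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H))
            dz = dz_all[:, t]
            dz[:, :H] = dc * g[:, t] * i[:, t] * (1.0 - i[:, t])
            dz[:, H:2 * H] = dc * c_prev * f[:, t] * (1.0 - f[:, t])
            dz[:, 2 * H:3 * H] = dc * i[:, t] * (1.0 - g[:, t] ** 2)
            dz[:, 3 * H:] = dh * tc[:, t] * o[:, t] * (1.0 - o[:, t])
            h_prev = h[:, t - 1] if t > 0 else np.zeros((B, H))
            self.dWh += h_prev.T @ dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f[:, t]
        self.dWx[...] = np.tensordot(x, dz_all, axes=([0, 1], [0, 1]))
        self.db[...] = dz_all.sum(axis=(0, 1))
        return dz_all @ self.Wx.T


class BiLSTM:
    """Bidirectional LSTM; output width 2*units (units if unidirectional)."""

    def __init__(self, in_channels: int, units: int, *,
                 rng: np.random.Generator, bidirectional: bool = True):
        if units < 1:
            raise ValidationError("units must be positive")
        self.units = units
        self.bidirectional = bidirectional
        self.fwd = _LSTMDirection(in_channels, units, rng)
        self.bwd = _LSTMDirection(in_channels, units, rng) if bidirectional else None

    @property
    def out_channels(self) -> int:
        return self.units * (2 if self.bidirectional else 1)

    def params(self):
        p = [self.fwd.Wx, self.fwd.Wh, self.fwd.b]
        if self.bwd is not None:
            p += [self.bwd.Wx, self.bwd.Wh, self.bwd.b]
        return p

    def grads(self):
        g = [self.fwd.dWx, self.fwd.dWh, self.fwd.db]
        if self.bwd is not None:
            g += [self.bwd.dWx, self.bwd.dWh, self.bwd.db]
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        if self.bwd is None:
            return hf
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.units
        if self.bwd is None:
            return self.fwd.backward(dy)
        dx = self.fwd.backward(dy[:, :, :H])
        dx = dx + self.bwd.backward(dy[:, ::-1, H:])[:, ::-1, :]
        return dx


class TimeDistributedDense:
    """Per-timestep affine map (batch, L, Cin) -> (batch, L, Cout)."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator):
        self.W = _glorot(rng, in_channels, out_channels, (in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.out_channels = out_channels

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = np.tensordot(self._x, dy, axes=([0, 1], [0, 1]))
        self.db[...] = dy.sum(axis=(0, 1))
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy over all (batch, timestep) positions.

    Returns ``(loss, dlogits)`` where dlogits already includes the softmax
    Jacobian, i.e. (p - target) / n_positions.
    """
    p = softmax(logits)
    n = logits.shape[0] * logits.shape[1]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    return float(loss), (p - onehot) / n


class Adam:
    """Adaptive-moment estimation over a flat list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValidationError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
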