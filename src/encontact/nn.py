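"""Minimal neural-network primitives used by the contact-prediction model.

Everything here operates on plain ``numpy`` arrays in float64 and implements both
the forward pass and the exact analytic backward pass; correctness is established
by finite-difference gradient checks in the test suite. The module provides

* the functional sequence operations of the model — full-width convolution of a
  one-hot matrix (ReLU-activated), non-overlapping max-pooling, and softmax
  attention pooling — usable standalone;
* batched layers (convolution tower, batch normalization, dropout, bidirectional
  LSTM, additive attention, dense) that compose into the full network;
* an Adam optimizer.

Shapes follow the convention (batch, time, channels).
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Functional primitives
# ---------------------------------------------------------------------------


def relu(z: np.ndarray) -> np.ndarray:
    """Rectified linear unit, max{0, z}."""
    return np.maximum(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # overflow-free: exp of a non-positive argument only
    e = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def cross_correlate(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Slide an M x 4 kernel over an L x 4 one-hot matrix (no activation).

    Position ``i`` of the result is ``sum_{m,n} w[m,n] * X[i+m, n]`` for
    ``i = 0..L-M``: the kernel consumes the full nucleotide width, so the scan
    runs along the sequence only.
    """
    X = np.asarray(X, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    L, C = X.shape
    M, N = kernel.shape
    if C != N:
        raise ValueError(f"channel mismatch: input has {C}, kernel has {N}")
    if M > L:
        raise ValueError(f"kernel length {M} exceeds sequence length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(X, M, axis=0)  # (L-M+1, C, M)
    return np.einsum("icm,mc->i", windows, kernel)


def conv_forward(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """ReLU-activated full-width convolution of a one-hot sequence matrix."""
    return relu(cross_correlate(X, kernel))


def max_pool(v: np.ndarray, W: int) -> np.ndarray:
    """Non-overlapping max-pooling with window ``W`` along the first axis.

    A trailing partial window is reduced over its members, so the output length
    is ``ceil(len(v) / W)``. Works on 1-D vectors and on (length, channels)
    arrays alike.
    """
    v = np.asarray(v)
    if W < 1:
        raise ValueError(f"pooling window must be >= 1, got {W}")
    n = v.shape[0]
    if n == 0:
        raise ValueError("cannot pool an empty vector")
    out = [v[i : i + W].max(axis=0) for i in range(0, n, W)]
    return np.stack(out) if v.ndim > 1 else np.asarray(out)


def attention_scores(H: np.ndarray, w: np.ndarray, b: float = 0.0) -> np.ndarray:
    """Scalar importance per time step: tanh of a learnable linear map of h_t."""
    return np.tanh(np.asarray(H) @ np.asarray(w) + b)


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax-normalize per-step scores into attention weights.

    Weights are strictly positive, sum to 1, and are invariant under adding a
    constant to all scores.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 1:
        raise ValueError("scores must be a 1-D vector, one entry per time step")
    if s.size == 0:
        raise ValueError("need at least one time step")
    e = np.exp(s - s.max())
    return e / e.sum()


def attention_pool(H: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Adaptive weighted average of hidden states: theta = sum_t alpha_t h_t."""
    H = np.asarray(H, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if H.shape[0] != alpha.shape[0]:
        raise ValueError(
            f"length mismatch: {H.shape[0]} hidden states, {alpha.shape[0]} weights"
        )
    return alpha @ H


# ---------------------------------------------------------------------------
# Layers with analytic backward passes
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ConvTower(Layer):
    """Full-width 1-D convolution over one-hot input: (B, L, 4) -> (B, L-M+1, K)."""

    def __init__(self, n_kernels: int, kernel_len: int, rng: np.random.Generator,
                 n_channels: int = 4, name: str = "conv"):
        self.M = kernel_len
        self.K = n_kernels
        self.C = n_channels
        self.W = Param(_glorot(rng, (kernel_len * n_channels, n_kernels)), f"{name}.W")
        self.b = Param(np.zeros(n_kernels), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    @property
    def kernels(self) -> np.ndarray:
        """Kernel tensor of shape (n_kernels, M, 4)."""
        return self.W.value.reshape(self.M, self.C, self.K).transpose(2, 0, 1)

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        # (B, L, C) -> (B, P, M*C) with P = L - M + 1
        w = np.lib.stride_tricks.sliding_window_view(X, self.M, axis=1)  # (B,P,C,M)
        return w.transpose(0, 1, 3, 2).reshape(X.shape[0], -1, self.M * self.C)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if X.shape[1] < self.M:
            raise ValueError(f"sequence length {X.shape[1]} < kernel length {self.M}")
        cols = self._im2col(np.asarray(X, dtype=np.float64))
        z = cols @ self.W.value + self.b.value
        self._cols, self._mask = cols, z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = np.where(self._mask, dout, 0.0)
        B, P, _ = dz.shape
        flat_cols = self._cols.reshape(-1, self.M * self.C)
        self.W.grad += flat_cols.T @ dz.reshape(-1, self.K)
        self.b.grad += dz.sum(axis=(0, 1))
        dcols = (dz @ self.W.value.T).reshape(B, P, self.M, self.C)
        dX = np.zeros((B, P + self.M - 1, self.C))
        for m in range(self.M):
            dX[:, m : m + P, :] += dcols[:, :, m, :]
        return dX


class MaxPoolLayer(Layer):
    """Non-overlapping max-pool along time, partial trailing window included."""

    def __init__(self, window: int):
        self.W = window

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        B, P, K = X.shape
        T = -(-P // self.W)
        pad = T * self.W - P
        Xp = np.concatenate([X, np.full((B, pad, K), -np.inf)], axis=1) if pad else X
        Xr = Xp.reshape(B, T, self.W, K)
        self._argmax = Xr.argmax(axis=2)
        self._in_shape = X.shape
        return np.take_along_axis(Xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, P, K = self._in_shape
        T = dout.shape[1]
        dXr = np.zeros((B, T, self.W, K))
        np.put_along_axis(dXr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        return dXr.reshape(B, T * self.W, K)[:, :P, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(n_channels), f"{name}.gamma")
        self.beta = Param(np.zeros(n_channels), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = X.mean(axis=(0, 1))
            var = X.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (X - mean) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not self._train:
            return dxhat / std
        n = xhat.shape[0] * xhat.shape[1]
        return (dxhat - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))) / std


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return X
        self._mask = (self.rng.random(X.shape) >= self.rate) / (1.0 - self.rate)
        return X * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class _LSTMDirection(Layer):
    """One direction of an LSTM; gate order (input, forget, output, cell)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 reverse: bool, name: str):
        H = n_hidden
        self.H, self.reverse = H, reverse
        self.Wx = Param(_glorot(rng, (n_in, 4 * H)), f"{name}.Wx")
        self.Wh = Param(_glorot(rng, (H, 4 * H)), f"{name}.Wh")
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias starts open
        self.b = Param(b, f"{name}.b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if self.reverse:
            X = X[:, ::-1, :]
        B, T, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        # input contribution for all time steps in one matmul
        Zx = X @ self.Wx.value + self.b.value
        self._cache = []
        self._X = X
        out = np.empty((B, T, H))
        for t in range(T):
            z = Zx[:, t, :] + h @ self.Wh.value
            gates = sigmoid(z[:, : 3 * H])
            i = gates[:, :H]
            f = gates[:, H : 2 * H]
            o = gates[:, 2 * H :]
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
            out[:, t, :] = h
        return out[:, ::-1, :] if self.reverse else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.reverse:
            dout = dout[:, ::-1, :]
        B, T, H = dout.shape
        dZ = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        Wh = self.Wh.value
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dc_next = dc * f
            dz = dZ[:, t, :]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H : 3 * H] = do * o * (1 - o)
            dz[:, 3 * H :] = dc * i * (1 - g * g)
            self.Wh.grad += h_prev.T @ dz
            dh_next = dz @ Wh.T
        dZ_flat = dZ.reshape(B * T, 4 * H)
        self.Wx.grad += self._X.reshape(B * T, -1).T @ dZ_flat
        self.b.grad += dZ_flat.sum(axis=0)
        dX = dZ @ self.Wx.value.T
        return dX[:, ::-1, :] if self.reverse else dX


class BiLSTM(Layer):
    """Bidirectional LSTM; outputs the channel-wise concatenation of both reads."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 name: str = "blstm"):
        self.fw = _LSTMDirection(n_in, n_hidden, rng, reverse=False, name=f"{name}.fw")
        self.bw = _LSTMDirection(n_in, n_hidden, rng, reverse=True, name=f"{name}.bw")
        self.H = n_hidden

    def params(self):
        return self.fw.params() + self.bw.params()

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate(
            [self.fw.forward(X, train), self.bw.forward(X, train)], axis=2
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.H
        return self.fw.backward(dout[:, :, :H]) + self.bw.backward(dout[:, :, H:])


class AttentionLayer(Layer):
    """Softmax attention over time with scores tanh(w . h_t + b); pools to (B, D)."""

    def __init__(self, n_in: int, rng: np.random.Generator, name: str = "attn"):
        self.w = Param(_glorot(rng, (n_in, 1))[:, 0], f"{name}.w")
        self.b = Param(np.zeros(1), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, H: np.ndarray, train: bool = False) -> np.ndarray:
        u = np.tanh(H @ self.w.value + self.b.value[0])  # (B, T)
        e = np.exp(u - u.max(axis=1, keepdims=True))
        alpha = e / e.sum(axis=1, keepdims=True)
        self._H, self._u, self.alpha = H, u, alpha
        return np.einsum("bt,btd->bd", alpha, H)

    def backward(self, dtheta: np.ndarray) -> np.ndarray:
        H, u, alpha = self._H, self._u, self.alpha
        dH = alpha[:, :, None] * dtheta[:, None, :]
        dalpha = np.einsum("bd,btd->bt", dtheta, H)
        du = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dpre = du * (1.0 - u * u)
        self.w.grad += np.einsum("bt,btd->d", dpre, H)
        self.b.grad += dpre.sum()
        dH += dpre[:, :, None] * self.w.value
        return dH


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "linear", name: str = "dense",
                 zero_init: bool = False):
        # zero_init gives an exactly uninformative start (logit 0 for every
        # input), removing any systematic drift in the first optimizer steps
        W = np.zeros((n_in, n_out)) if zero_init else _glorot(rng, (n_in, n_out))
        self.W = Param(W, f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        z = X @ self.W.value + self.b.value
        self._X = X
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0.0)
        self.W.grad += self._X.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def binary_cross_entropy_from_logits(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean BCE loss and its gradient w.r.t. the logits."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return loss, (p - y) / y.shape[0]
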