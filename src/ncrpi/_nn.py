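"""Minimal feed-forward/recurrent network core with manual backpropagation.

Implements exactly the layer set the classifier needs — 1-D convolution
(same padding, stride 1), ReLU, max pooling, batch normalization, dropout,
a bidirectional LSTM returning the final hidden states, dense layers and a
softmax cross-entropy head — together with Adam and plain SGD.  All math is
numpy; every layer's backward pass is verified against finite differences
in the test suite.

Shapes are channels-last throughout: convolutional layers operate on
(batch, length, channels) and the BLSTM on (batch, time, features), so the
conv stack feeds the recurrence without transposes.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # whether L2 weight decay applies


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Layer):
    def __init__(self, rng, d_in: int, d_out: int, dtype=np.float32):
        self.W = Param(glorot(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype), decay=False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv1d(Layer):
    """Stride-1 'same' convolution on channels-last (batch, length, channels)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, dtype=np.float32):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in, fan_out = c_in * kernel, c_out * kernel
        # rows ordered (kernel offset, input channel)
        self.W = Param(glorot(rng, fan_in, fan_out, (kernel * c_in, c_out), dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype), decay=False)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        B, L, C = x.shape
        k = self.kernel
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # windows: (B, L, C, k) -> cols (B, L, k, C) flattened; the copy is
        # cache-friendly because the innermost C axis is contiguous
        cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B * L, k * C)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.W.value + self.b.value
        return y.reshape(B, L, self.c_out)

    def backward(self, grad):
        B, L, C = self._in_shape
        k = self.kernel
        g = grad.reshape(B * L, self.c_out)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + k - 1, C), dtype=grad.dtype)
        for t in range(k):
            dxp[:, t : t + L, :] += dcols[:, :, t, :]
        return dxp[:, self.pad_left : self.pad_left + L, :]


class MaxPool1d(Layer):
    """Non-overlapping max pooling over the length axis of (B, L, C);
    a trailing remainder is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training):
        B, L, C = x.shape
        n = L // self.size
        if n == 0:
            raise ValueError(
                f"pooling size {self.size} would empty a length-{L} feature map; "
                "reduce pool_size for this input dimension"
            )
        self._in_shape = x.shape
        trimmed = x[:, : n * self.size, :].reshape(B, n, self.size, C)
        self._argmax = trimmed.argmax(axis=2)
        return trimmed.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        n = L // self.size
        dtrim = np.zeros((B, n, self.size, C), dtype=grad.dtype)
        np.put_along_axis(dtrim, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : n * self.size, :] = dtrim.reshape(B, n * self.size, C)
        return dx


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and length of (B, L, C)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(channels, dtype=dtype), decay=False)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma.value
        if not self._training:
            return dxhat / self._std
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1), keepdims=True)
        ) / self._std
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class _LSTMDirection:
    """One direction of the BLSTM; returns the final hidden state."""

    def __init__(self, rng, d_in: int, hidden: int, dtype=np.float32):
        self.hidden = hidden
        d = d_in + hidden
        self.W = Param(glorot(rng, d, 4 * hidden, (d, 4 * hidden), dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias init
        self.b = Param(b, decay=False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        # x: (B, T, D); returns h_T (B, H)
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._cache = []
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ self.W.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((xh, i, f, g, o, c, tanh_c))
            h, c = h_new, c_new
        self._T, self._B, self._D = T, B, D
        return h

    def backward(self, dh_T):
        T, B, D, H = self._T, self._B, self._D, self.hidden
        dx = np.zeros((B, T, D), dtype=dh_T.dtype)
        dh = dh_T.copy()
        dc = np.zeros((B, H), dtype=dh_T.dtype)
        # gradients vanish exponentially through long BPTT chains; flush
        # subnormal magnitudes to zero (they are meaningless and make x86
        # arithmetic orders of magnitude slower)
        tiny = 1e-30
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tanh_c = self._cache[t]
            dh[np.abs(dh) < tiny] = 0.0
            dc[np.abs(dc) < tiny] = 0.0
            do = dh * tanh_c
            dct = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.W.grad += xh.T @ dz
            self.b.grad += dz.sum(axis=0)
            dxh = dz @ self.W.value.T
            dx[:, t, :] = dxh[:, :D]
            dh = dxh[:, D:]
        dx[np.abs(dx) < tiny] = 0.0
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, T, D); output = concat of both final states."""

    def __init__(self, rng, d_in: int, hidden: int, dtype=np.float32):
        self.fwd = _LSTMDirection(rng, d_in, hidden, dtype)
        self.bwd = _LSTMDirection(rng, d_in, hidden, dtype)
        self.hidden = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training):
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, grad):
        H = self.hidden
        dx_f = self.fwd.backward(grad[:, :H])
        dx_b = self.bwd.backward(grad[:, H:])
        return dx_f + dx_b[:, ::-1, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy over the 2-way softmax and its gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Optimizer:
    def __init__(self, params: List[Param], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def _decayed_grad(self, p: Param) -> np.ndarray:
        if p.decay and self.weight_decay:
            return p.grad + self.weight_decay * p.value
        return p.grad

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def step(self):
        for p in self.params:
            p.value -= self.lr * self._decayed_grad(p)


class Adam(Optimizer):
    def __init__(self, params, lr, weight_decay=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = self._decayed_grad(p)
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
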