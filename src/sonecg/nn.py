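"""Minimal 1D convolutional network engine (numpy, CPU).

Implements exactly the pieces the audio-to-ECG demodulator needs: stride-1
"same" 1D convolution (im2col + BLAS matmul), non-overlapping max pooling,
inverted dropout, and the Adam optimizer.  Data layout is channels-last:
``(batch, length, channels)`` in float32.

The engine is intentionally small and deterministic: given the same seed
and inputs it reproduces training runs bit-for-bit on a single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv1D:
    """Stride-1 'same' convolution; weights stored as (C_in*M, C_out)."""

    def __init__(self, kernel_size: int, in_channels: int, out_channels: int):
        self.m = int(kernel_size)
        self.c_in = int(in_channels)
        self.c_out = int(out_channels)
        self.w = np.zeros((self.c_in * self.m, self.c_out), dtype=np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)
        self.dw = None
        self.db = None
        self._cols = None
        self._shape = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def init_glorot(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.m
        limit = np.sqrt(6.0 / (fan_in + self.c_out))
        self.w = rng.uniform(-limit, limit, self.w.shape).astype(np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    def kernels(self) -> np.ndarray:
        """Weights as (M, C_in, C_out) for inspection."""
        return self.w.reshape(self.c_in, self.m, self.c_out).transpose(1, 0, 2)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        bsz, length, _ = x.shape
        pad_l = (self.m - 1) // 2
        pad_r = self.m - 1 - pad_l
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        # (B, L, C, M) view -> (B*L, C*M) im2col copy
        win = sliding_window_view(xp, self.m, axis=1)
        cols = np.ascontiguousarray(win).reshape(bsz * length,
                                                 self.c_in * self.m)
        self._cols = cols if training else None
        self._shape = (bsz, length)
        out = cols @ self.w + self.b
        return out.reshape(bsz, length, self.c_out)

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        bsz, length = self._shape
        d2 = dout.reshape(bsz * length, self.c_out)
        self.dw = self._cols.T @ d2
        self.db = d2.sum(axis=0)
        if not need_dx:
            self._cols = None
            return None
        g = (d2 @ self.w.T).reshape(bsz, length, self.c_in, self.m)
        pad_l = (self.m - 1) // 2
        dxp = np.zeros((bsz, length + self.m - 1, self.c_in),
                       dtype=np.float32)
        for j in range(self.m):
            dxp[:, j:j + length, :] += g[:, :, :, j]
        self._cols = None
        return dxp[:, pad_l:pad_l + length, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class MaxPool1D:
    """Non-overlapping max pooling with window ``k`` along the length axis."""

    def __init__(self, k: int):
        self.k = int(k)
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        bsz, length, ch = x.shape
        if length % self.k:
            raise ValueError(
                f"pool window {self.k} does not divide length {length}")
        xr = x.reshape(bsz, length // self.k, self.k, ch)
        if training:
            self._idx = xr.argmax(axis=2)
            self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        bsz, length, ch = self._shape
        dxr = np.zeros((bsz, length // self.k, self.k, ch), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[:, :, None, :],
                          dout[:, :, None, :], axis=2)
        return dxr.reshape(bsz, length, ch)

    def params(self):
        return []

    def grads(self):
        return []


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = float(rate)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        if self._mask is None:
            return dout
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class Sequential:
    """Plain layer stack with reverse-order backpropagation."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            if isinstance(layer, Dropout):
                out = layer.forward(out, training=training, rng=rng)
            else:
                out = layer.forward(out, training=training)
        return out

    def backward(self, dout: np.ndarray) -> None:
        first_conv = next(l for l in self.layers if isinstance(l, Conv1D))
        grad = dout.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad, need_dx=layer is not first_conv)
            if grad is None:
                break

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs "
                                 f"{w.shape}")
            p[...] = w


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2 ** self.t) \
            / (1 - self.beta1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
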