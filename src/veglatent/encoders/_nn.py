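"""Small feed-forward / 1-D convolutional network core in NumPy.

Only what the autoencoders need: dense layers, 1-D convolutions over a
channels-by-steps sequence, ReLU, reshapes, nearest-neighbour upsampling and
an Adam optimizer.  Everything runs in float64 for deterministic,
numerically checkable gradients.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer; subclasses fill ``params`` and ``grads`` (aligned lists)."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Conv1D(Layer):
    """1-D convolution on (batch, channels, length) with zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
    ) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.standard_normal((c_out, c_in, kernel)) * scale
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        l_out = (length + 2 * p - k) // s + 1
        idx = np.arange(l_out)[:, None] * s + np.arange(k)[None, :]
        cols = xp[:, :, idx]  # (n, c_in, l_out, k)
        # im2col matmul: (n*l_out, c_in*k) @ (c_in*k, c_out)
        self._cols2 = cols.transpose(0, 2, 1, 3).reshape(n * l_out, c * k)
        self._in_shape = x.shape
        self._l_out = l_out
        self._idx = idx
        out = self._cols2 @ self.W.reshape(self.W.shape[0], c * k).T + self.b
        return out.reshape(n, l_out, -1).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        k, p, l_out = self.kernel, self.pad, self._l_out
        c_out = self.W.shape[0]
        dflat = dout.transpose(0, 2, 1).reshape(n * l_out, c_out)
        self.grads[0][...] = (self._cols2.T @ dflat).T.reshape(c_out, c, k)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(c_out, c * k)).reshape(n, l_out, c, k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c, l_out, k)
        dxp = np.zeros((n * c, length + 2 * p))
        np.add.at(
            dxp,
            (np.arange(n * c)[:, None], self._idx.ravel()[None, :]),
            dcols.reshape(n * c, -1),
        )
        dxp = dxp.reshape(n, c, length + 2 * p)
        return dxp[:, :, p:length + p] if p else dxp


class Upsample1D(Layer):
    """Nearest-neighbour upsampling along the sequence axis."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length = dout.shape
        return dout.reshape(n, c, length // self.factor, self.factor).sum(axis=3)


class ToSequence(Layer):
    """(batch, steps*channels) month-major vector -> (batch, channels, steps)."""

    def __init__(self, steps: int, channels: int) -> None:
        super().__init__()
        self.steps, self.channels = steps, channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(-1, self.steps, self.channels).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.transpose(0, 2, 1).reshape(-1, self.steps * self.channels)


class FromSequence(Layer):
    """(batch, channels, steps) -> month-major (batch, steps*channels)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.transpose(0, 2, 1).reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, steps = self._shape
        return dout.reshape(n, steps, c).transpose(0, 2, 1)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Unflatten(Layer):
    def __init__(self, channels: int, length: int) -> None:
        super().__init__()
        self.channels, self.length = channels, length

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(-1, self.channels, self.length)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(dout.shape[0], -1)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
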