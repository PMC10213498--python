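"""Minimal feed-forward network engine (numpy, float32).

Purpose-built for the dispersal CNN: 1-D valid convolutions whose kernel
spans all input channels, average pooling, dense layers, ReLU, dropout,
mean-squared-error loss and the Adam optimiser.  Weights use He/Glorot
fan-based initialisation from a seeded generator, so construction and
training are fully reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "Dropout", "Conv1D", "AvgPool1D", "Flatten",
           "Sequential", "Adam"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "he"):
        super().__init__()
        std = np.sqrt((2.0 if scale == "he" else 1.0) / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(np.float32)

    def backward(self, g):
        if self.rate == 0.0:
            return g
        return g * self._mask


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1, kernel spanning all input channels."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = rng.normal(0.0, std, size=(kernel * c_in, filters)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        # x: (B, L, C) -> (B, L-k+1, k*C)
        k = self.kernel
        cols = [x[:, i: x.shape[1] - k + 1 + i, :] for i in range(k)]
        return np.concatenate(cols, axis=2)

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, g):
        B, Lo, F = g.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[2])
        g2 = g.reshape(-1, F)
        self.grads[0][...] = cols2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        gcols = g @ self.W.T  # (B, Lo, k*C)
        B_, L, C = self._x_shape
        dx = np.zeros(self._x_shape, dtype=np.float32)
        k = self.kernel
        for i in range(k):
            dx[:, i: L - k + 1 + i, :] += gcols[:, :, i * C: (i + 1) * C]
        return dx


class AvgPool1D(Layer):
    """Average pooling, width == stride, trailing remainder dropped."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x, train):
        B, L, C = x.shape
        Lo = L // self.width
        self._in_shape = x.shape
        self._Lo = Lo
        return x[:, : Lo * self.width, :].reshape(B, Lo, self.width, C).mean(axis=2)

    def backward(self, g):
        B, L, C = self._in_shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        up = np.repeat(g / self.width, self.width, axis=1)
        dx[:, : up.shape[1], :] = up
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
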