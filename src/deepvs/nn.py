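"""Minimal deterministic neural-network core (numpy).

Both screening classifiers are small enough that a hand-rolled, fully
deterministic numpy implementation is preferable to a heavyweight framework:
single-threaded training is exactly reproducible from a seed, which the test
contracts require. Provides dense and 1-D convolutional layers, identity-skip
residual blocks, Adam, and binary cross-entropy with logits.

Shapes: dense layers take ``(N, D)``; conv layers take ``(N, L, C)`` with
``L`` the sequence (row) axis and ``C`` channels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Layer:
    """Base layer: ``params`` and ``grads`` are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init, ReLU default
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """Same-padded 1-D convolution over ``(N, L, C_in)`` with odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        N, L, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp, self._L = xp, L
        out = np.zeros((N, L, self.W.shape[2]))
        for t in range(self.k):
            out += xp[:, t:t + L, :] @ self.W[t]
        return out + self.b

    def backward(self, grad):
        L, k = self._L, self.k
        xp = self._xp
        dxp = np.zeros_like(xp)
        for t in range(k):
            self.grads[0][t] = np.einsum("nlc,nld->cd", xp[:, t:t + L, :], grad)
            dxp[:, t:t + L, :] += grad @ self.W[t].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        p = k // 2
        return dxp[:, p:p + L, :]


class ResidualBlock1D(Layer):
    """y = relu(x + conv(relu(conv(x)))) with matching channel counts."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1D(channels, channels, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(channels, channels, kernel, rng)
        self.relu_out = ReLU()
        for lyr in (self.conv1, self.conv2):
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + h)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + gh


class GlobalAvgPool1D(Layer):
    def forward(self, x):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._L, axis=1) / self._L


class Network:
    """A plain layer stack trained with Adam on binary cross-entropy.

    The final layer must output one logit per sample; probabilities are
    produced by a sigmoid at predict time.
    """

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        self.loss_history: list[float] = []

    # -- plumbing -----------------------------------------------------------
    def _params(self):
        for lyr in self.layers:
            yield from zip(lyr.params, lyr.grads)

    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        h = X
        for lyr in self.layers:
            h = lyr.forward(h)
        return h.reshape(-1)

    def _backward(self, grad: np.ndarray) -> None:
        g = grad
        for lyr in reversed(self.layers):
            g = lyr.backward(g)

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 30,
            batch_size: int = 64, learning_rate: float = 1e-3,
            weight_decay: float = 0.0, seed: int = 0) -> "Network":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(seed)

        m = [np.zeros_like(p) for p, _ in self._params()]
        v = [np.zeros_like(p) for p, _ in self._params()]
        t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        n = len(y)
        for _epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                z = self.forward_logits(xb)
                p = sigmoid(z)
                # BCE with logits; gradient is (p - y)/B
                loss = -np.mean(yb * np.log(p + 1e-12)
                                + (1 - yb) * np.log(1 - p + 1e-12))
                losses.append(float(loss))
                grad = ((p - yb) / len(yb)).reshape(-1, 1)
                # expand grad back to the last layer's output shape
                self._backward(grad)
                t += 1
                for i, (param, g) in enumerate(self._params()):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1 ** t)
                    vhat = v[i] / (1 - beta2 ** t)
                    # decoupled (AdamW-style) weight decay
                    param -= learning_rate * (mhat / (np.sqrt(vhat) + eps)
                                              + weight_decay * param)
            self.loss_history.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = [sigmoid(self.forward_logits(X[i:i + batch_size]))
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self._params()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = [p for p, _ in self._params()]
        if len(own) != len(arrays):
            raise ValueError("state shape mismatch")
        for p, a in zip(own, arrays):
            if p.shape != np.asarray(a).shape:
                raise ValueError("state shape mismatch")
            p[...] = a


def mlp(n_in: int, hidden: Sequence[int], seed: int = 0) -> Network:
    """Fully connected ReLU stack with a single-logit head."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    prev = n_in
    for width in hidden:
        layers += [Dense(prev, width, rng), ReLU()]
        prev = width
    layers.append(Dense(prev, 1, rng))
    return Network(layers)


def conv_resnet(c_in: int, channels: int = 16, n_blocks: int = 4,
                kernel: int = 3, seed: int = 0) -> Network:
    """Small conv net with identity skip connections over contact rows."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [Conv1D(c_in, channels, kernel, rng), ReLU()]
    for _ in range(n_blocks):
        layers.append(ResidualBlock1D(channels, kernel, rng))
    layers += [GlobalAvgPool1D(), Dense(channels, 1, rng)]
    return Network(layers)
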