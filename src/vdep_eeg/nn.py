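"""A compact NumPy implementation of a small 2-D convolutional network.

The decoder is an image-style binary classifier: a stack of 3x3
convolution blocks (same padding, ReLU, 2x2 max-pool) followed by one
dense hidden layer and a single sigmoid output, trained with Adam on a
binary cross-entropy objective.  Convolutions run as im2col GEMMs in
float32; the [0, 1] inputs are centred to [-0.5, 0.5] at the input
layer, which markedly speeds up convergence.  Training is
deterministic for a fixed seed.
"""
from __future__ import annotations

import numpy as np

from .config import ModelConfig

__all__ = ["CNNClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv2D:
    """Same-padding stride-1 convolution on NHWC arrays (im2col GEMM)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He initialisation
        self.W = (rng.standard_normal((k * k * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols = np.empty((n, h, w, k * k * c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                o = (di * k + dj) * c
                cols[..., o : o + c] = xp[:, di : di + h, dj : dj + w, :]
        self._cols = cols.reshape(-1, k * k * c)
        self._shape = (n, h, w, c)
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, c = self._shape
        dflat = dout.reshape(-1, self.W.shape[1])
        self.db = dflat.sum(axis=0)
        self.dW = self._cols.T @ dflat
        dcols = (dflat @ self.W.T).reshape(n, h, w, k * k * c)
        self._cols = None
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                o = (di * k + dj) * c
                dxp[:, di : di + h, dj : dj + w, :] += dcols[..., o : o + c]
        return dxp[:, pad : pad + h, pad : pad + w, :]

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []
    grads: list = []


class _MaxPool2x2:
    """2x2 max-pooling.  Gradient is routed by value equality, which is
    exact up to ties; the preceding ReLU zeroes any gradient sent to a
    tied-at-zero position, and ties between positive activations have
    measure zero."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._x6 = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = self._x6.max(axis=(2, 4))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, _, w2, _, c = self._x6.shape
        mask = self._x6 == self._out[:, :, None, :, None, :]
        g = mask * dout[:, :, None, :, None, :]
        self._x6 = self._out = None
        return g.reshape(n, h2 * 2, w2 * 2, c)

    params: list = []
    grads: list = []


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: list = []
    grads: list = []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class CNNClassifier:
    """Binary CNN on (n, height, width, 1) inputs in [0, 1]."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int] = (128, 32)):
        self.cfg = cfg
        h, w = input_shape
        depth = len(cfg.conv_filters)
        if h % 2**depth or w % 2**depth:
            raise ValueError("input dims must be divisible by 2^n_conv_blocks")
        rng = np.random.default_rng(cfg.seed)
        self.layers: list = []
        c_in = 1
        for c_out in cfg.conv_filters:
            self.layers += [_Conv2D(c_in, c_out, cfg.kernel_size, rng), _ReLU(), _MaxPool2x2()]
            c_in = c_out
            h, w = h // 2, w // 2
        self.layers += [_Flatten(), _Dense(h * w * c_in, cfg.dense_units, rng), _ReLU(),
                        _Dense(cfg.dense_units, 1, rng)]
        self._rng = rng
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- plumbing ---------------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def _grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def _forward(self, x: np.ndarray) -> np.ndarray:
        x = x - np.float32(0.5)  # center the [0, 1] inputs once, up front
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]  # logits

    def _backward(self, dlogit: np.ndarray) -> None:
        d = dlogit[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- API --------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None) -> "CNNClassifier":
        """Mini-batch Adam with optional early stopping on validation loss."""
        cfg = self.cfg
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        opt = _Adam(self._params(), cfg.learning_rate)
        monitor = X_val is not None and y_val is not None
        best_loss, best_params, wait = np.inf, None, 0
        n = len(X)
        for _ in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                z = self._forward(xb).astype(np.float64)
                losses.append(float(np.mean(np.logaddexp(0.0, z) - yb * z)))
                self._backward(((_sigmoid(z) - yb) / len(yb)).astype(np.float32))
                opt.step(self._grads())
            self.history["train_loss"].append(float(np.mean(losses)))
            if monitor:
                vloss = self._loss(X_val, y_val)
                self.history["val_loss"].append(vloss)
                if vloss < best_loss - 1e-6:
                    best_loss, wait = vloss, 0
                    best_params = [p.copy() for p in self._params()]
                else:
                    wait += 1
                    if wait > cfg.patience:
                        break
        if best_params is not None:
            for p, bp in zip(self._params(), best_params):
                p[...] = bp
        return self

    def _loss(self, X: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
        tot, n = 0.0, len(X)
        for lo in range(0, n, batch):
            z = self._forward(np.asarray(X[lo : lo + batch], dtype=np.float32))
            yb = y[lo : lo + batch]
            tot += float(np.sum(np.logaddexp(0.0, z) - yb * z))
        return tot / n

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        """Class-1 probability (sigmoid output) per sample."""
        out = np.empty(len(X))
        for lo in range(0, len(X), batch):
            out[lo : lo + batch] = _sigmoid(self._forward(np.asarray(X[lo : lo + batch], dtype=np.float32)))
        return out
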