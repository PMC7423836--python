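"""Minimal seeded NumPy neural-network backend for the CNN classifier.

Implements exactly what the classifier needs — 2-D convolution (im2col),
2x2 max pooling, dense layers with L1/L2 kernel regularization, ReLU /
tanh / per-layer softmax activations, softmax cross-entropy and Adam —
with deterministic seeded initialization and shuffling.  Single-threaded
NumPy makes training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2", "Activation", "Flatten", "Dense", "Model"]

_F = np.float32


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


class Conv2D(Layer):
    """Same-padded stride-1 convolution, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(0.0, std, size=(c_out, c_in * k * k)).astype(_F)
        self.params["b"] = np.zeros(c_out, dtype=_F)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)
        if train:
            self._cols = cols
        n, _, h, w = x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = (g.T @ self._cols).astype(_F)
        self.grads["b"] = g.sum(axis=0).astype(_F)
        dcols = (g @ self.params["W"]).reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None].astype(_F), axis=-1)
        return (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Activation(Layer):
    """'relu', 'tanh', or 'softmax' (normalizing over the channel/feature axis)."""

    def __init__(self, kind: str):
        super().__init__()
        kind = kind.lower()
        if kind not in ("relu", "tanh", "softmax"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        elif self.kind == "tanh":
            out = np.tanh(x)
        else:
            z = x - x.max(axis=1, keepdims=True)
            e = np.exp(z)
            out = e / e.sum(axis=1, keepdims=True)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return grad * (self._out > 0)
        if self.kind == "tanh":
            return grad * (1.0 - self._out**2)
        s = self._out
        return s * (grad - (grad * s).sum(axis=1, keepdims=True))


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional L1/L2 kernel regularization."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        regularizer: str | None = None,
        reg_factor: float = 0.0,
    ):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, std, size=(n_in, n_out)).astype(_F)
        self.params["b"] = np.zeros(n_out, dtype=_F)
        if regularizer is not None and regularizer not in ("l1", "l2"):
            raise ValueError(f"unknown regularizer {regularizer!r}")
        self.regularizer = regularizer
        self.reg_factor = float(reg_factor)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w = self.params["W"]
        dw = self._x.T @ grad
        if self.regularizer == "l1":
            dw = dw + self.reg_factor * np.sign(w)
        elif self.regularizer == "l2":
            dw = dw + 2.0 * self.reg_factor * w
        self.grads["W"] = dw.astype(_F)
        self.grads["b"] = grad.sum(axis=0).astype(_F)
        self._x = None
        return grad @ w.T

    def reg_loss(self) -> float:
        w = self.params["W"]
        if self.regularizer == "l1":
            return float(self.reg_factor * np.abs(w).sum())
        if self.regularizer == "l2":
            return float(self.reg_factor * (w**2).sum())
        return 0.0


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Model:
    """A plain sequential network trained with Adam on softmax cross-entropy."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._adam_m: dict = {}
        self._adam_v: dict = {}
        self._adam_t = 0

    @property
    def n_weights(self) -> int:
        return int(sum(p.size for lay in self.layers for p in lay.params.values()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_softmax(self.forward(x[i : i + batch_size].astype(_F))))
        return np.concatenate(out, axis=0)

    def _step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        logits = self.forward(x, train=True)
        probs = _softmax(logits)
        n = len(y)
        data_loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        reg = sum(lay.reg_loss() for lay in self.layers)
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for lay in reversed(self.layers):
            grad = lay.backward(grad.astype(_F))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for li, lay in enumerate(self.layers):
            for name, p in lay.params.items():
                key = (li, name)
                g = lay.grads[name]
                m = self._adam_m.get(key)
                v = self._adam_v.get(key)
                if m is None:
                    m = np.zeros_like(p)
                    v = np.zeros_like(p)
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._adam_m[key], self._adam_v[key] = m, v
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(_F)
        return data_loss + reg

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> dict:
        """Train in place; returns a history of per-epoch mean loss and accuracy."""
        x = np.asarray(x, dtype=_F)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        history = {"loss": [], "accuracy": []}
        for _ in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), batch_size):
                idx = order[i : i + batch_size]
                losses.append(self._step(x[idx], y[idx], lr))
            pred = self.predict_proba(x).argmax(axis=1)
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(float((pred == y).mean()))
        return history
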