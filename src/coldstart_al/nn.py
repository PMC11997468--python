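"""Minimal feed-forward network engine used by all model roles.

Implements exactly the pieces the benchmark needs — dense and 3x3 "same"
convolution layers, 2x2 max-pooling, ReLU, inverted dropout, softmax
cross-entropy with class weights, mean-squared-error, and SGD with
momentum — on plain numpy arrays. Everything is driven by an explicit
``numpy.random.Generator`` so that training is bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Network",
    "softmax",
    "weighted_ce_loss_grad",
    "mse_loss_grad",
    "SGDMomentum",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He initialization; fine for both ReLU trunks and linear heads
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x, *, train, rng):
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        x = self._x
        self.grads[0][...] = x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 ("same")."""

    K = 3
    PAD = 1

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * self.K * self.K
        w = rng.standard_normal((c_out, c_in, self.K, self.K)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cols: np.ndarray | None = None

    @staticmethod
    def _windows(x: np.ndarray, k: int, pad: int) -> np.ndarray:
        # x: (N, C, H, W) -> (N, C, H, W, k, k) strided view, no copy
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        return sliding_window_view(xp, (k, k), axis=(2, 3))

    def forward(self, x, *, train, rng):
        cols = self._windows(x, self.K, self.PAD)
        if train:
            self._cols = cols
        out = np.einsum("nchwij,ocij->nohw", cols, self.params[0], optimize=True)
        return out + self.params[1][None, :, None, None]

    def backward(self, dout):
        w = self.params[0]
        self.grads[0][...] = np.einsum("nchwij,nohw->ocij", self._cols, dout, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        # dX: full correlation of dout with the spatially flipped kernel
        cols_y = self._windows(dout, self.K, self.PAD)
        return np.einsum("nohwij,ocij->nchw", cols_y, w[:, :, ::-1, ::-1], optimize=True)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; input height/width must be even."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        return (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )

    def forward(self, x, *, train, rng):
        blocks = self._blocks(x)
        idx = blocks.argmax(axis=-1)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dblocks, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dblocks.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x, *, train, rng):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when inactive (deterministic inference)."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x, *, train, rng):
        if not train or self.p == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, *, train, rng):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Network:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def stochastic_forward(self, x: np.ndarray, rng: np.random.Generator, dropout_p: float | None = None) -> np.ndarray:
        """Forward pass with dropout active (gradients are not cached).

        Used for Monte-Carlo-dropout inference; ``dropout_p`` temporarily
        overrides every dropout layer's rate when given.
        """
        out = x
        for layer in self.layers:
            if isinstance(layer, Dropout):
                p = layer.p if dropout_p is None else dropout_p
                if p > 0.0:
                    mask = (rng.random(out.shape) >= p) / (1.0 - p)
                    out = out * mask
            else:
                out = layer.forward(out, train=False, rng=rng)
        return out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def weighted_ce_loss_grad(logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy.

    Per-sample losses are weighted by the weight of the true class and
    normalized by the total weight (the standard weighted-mean convention),
    so the gradient scale is insensitive to the weight vector's scale.
    """
    n = logits.shape[0]
    p = softmax(logits)
    w = class_weights[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


def mse_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class SGDMomentum:
    def __init__(self, params: list[np.ndarray], lr: float, momentum: float) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
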