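"""The three model roles and their shared training loop.

* ``ImageClassifier`` — a small dropout-equipped CNN over raw pixels with a
  two-class softmax head (desk-scale stand-in for a deep pixel backbone).
* ``EmbeddingClassifier`` — a three-layer perceptron (hidden widths 512 and
  256) over frozen embeddings, same probability contract.
* ``UncertaintyEstimator`` — the CNN trunk with its output layer widened to
  the embedding dimensionality, trained with MSE as the proxy regression
  task whose MC-dropout inference variance scores label-free uncertainty.

Training is SGD with momentum, class-weighted cross-entropy (weight of
class c = n_total / (2 n_c)), learning-rate halving after ``lr_patience``
epochs without loss improvement, and early stopping after
``early_stop_patience`` epochs without improvement. The monitored
quantity is the training loss: the benchmark's cold-start setting has no
validation set by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .encoders import EmbeddingMatrix

__all__ = [
    "TrainingConfig",
    "ImageClassifier",
    "EmbeddingClassifier",
    "UncertaintyEstimator",
    "class_weights",
    "train_classifier",
    "train_uncertainty_estimator",
    "predict_proba",
    "SingleClassWarning",
]

#: minimum loss decrease that counts as an improvement
MIN_IMPROVEMENT = 1e-5


class SingleClassWarning(UserWarning):
    """Raised (as a warning) when a labeled set contains one class only."""


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 10
    max_epochs: int = 200
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 20
    loss: str = "weighted_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.loss not in ("weighted_cross_entropy", "mean_squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


ESTIMATOR_CONFIG = TrainingConfig(learning_rate=1e-4, loss="mean_squared_error")


def _cnn_layers(height: int, width: int, n_out: int, dropout_rate: float, rng: np.random.Generator) -> list:
    if height % 4 or width % 4:
        raise ValueError("image height and width must be divisible by 4 for the CNN trunk")
    flat = 16 * (height // 4) * (width // 4)
    return [
        nn.Conv2d(1, 8, rng),
        nn.ReLU(),
        nn.MaxPool2d(),
        nn.Conv2d(8, 16, rng),
        nn.ReLU(),
        nn.MaxPool2d(),
        nn.Flatten(),
        nn.Dropout(dropout_rate),
        nn.Dense(flat, 64, rng),
        nn.ReLU(),
        nn.Dropout(dropout_rate),
        nn.Dense(64, n_out, rng),
    ]


@dataclass
class _ModelBase:
    network: nn.Network | None = None
    fitted: bool = False

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ImageClassifier(_ModelBase):
    """Small CNN with dropout and a 2-class softmax head."""

    image_height: int = 32
    image_width: int = 32
    dropout_rate: float = 0.5

    def build(self, rng: np.random.Generator) -> None:
        self.network = nn.Network(
            _cnn_layers(self.image_height, self.image_width, 2, self.dropout_rate, rng)
        )

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:  # single image
            x = x[None]
        return x[:, None, :, :]


@dataclass
class EmbeddingClassifier(_ModelBase):
    """MLP-3 over embeddings: hidden widths 512 and 256, softmax head."""

    input_dim: int = 32
    hidden: tuple[int, int] = (512, 256)

    def build(self, rng: np.random.Generator) -> None:
        h1, h2 = self.hidden
        self.network = nn.Network(
            [
                nn.Dense(self.input_dim, h1, rng),
                nn.ReLU(),
                nn.Dense(h1, h2, rng),
                nn.ReLU(),
                nn.Dense(h2, 2, rng),
            ]
        )

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None]
        return x


@dataclass
class UncertaintyEstimator(_ModelBase):
    """CNN trunk with an ``embedding_dim``-wide linear output, MSE-trained."""

    image_height: int = 32
    image_width: int = 32
    embedding_dim: int = 32
    dropout_rate: float = 0.5

    def build(self, rng: np.random.Generator) -> None:
        self.network = nn.Network(
            _cnn_layers(self.image_height, self.image_width, self.embedding_dim, self.dropout_rate, rng)
        )

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return x[:, None, :, :]

    def mc_forward(self, images: np.ndarray, dropout_p: float, rng: np.random.Generator) -> np.ndarray:
        """One stochastic forward pass with dropout active at ``dropout_p``."""
        if not self.fitted:
            raise RuntimeError("estimator must be trained before MC-dropout inference")
        return self.network.stochastic_forward(self._prepare(images), rng, dropout_p=dropout_p)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights: w_c = n_total / (2 n_c)."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    counts = np.bincount(labels, minlength=2)
    weights = np.ones(2)
    nz = counts > 0
    weights[nz] = n / (2.0 * counts[nz])
    return weights


def _train(
    model: _ModelBase,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
    weights: np.ndarray | None,
    warm_start: bool = False,
) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    if not (warm_start and model.fitted):
        model.build(rng)
    net = model.network
    x = model._prepare(inputs)
    n = x.shape[0]
    opt = nn.SGDMomentum(net.params, config.learning_rate, config.momentum)

    best = np.inf
    since_improvement = 0
    since_lr_drop = 0
    log: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = net.forward(x[idx], train=True, rng=rng)
            if config.loss == "weighted_cross_entropy":
                loss, dout = nn.weighted_ce_loss_grad(out, targets[idx], weights)
            else:
                loss, dout = nn.mse_loss_grad(out, targets[idx])
            net.backward(dout)
            opt.step(net.grads)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        log.append({"epoch": epoch, "loss": epoch_loss, "lr": opt.lr})
        if best - epoch_loss >= MIN_IMPROVEMENT:
            best = epoch_loss
            since_improvement = 0
            since_lr_drop = 0
        else:
            since_improvement += 1
            since_lr_drop += 1
        if since_improvement >= config.early_stop_patience:
            break
        if since_lr_drop >= config.lr_patience:
            opt.lr *= config.lr_decay_factor
            since_lr_drop = 0
    model.fitted = True
    return pd.DataFrame(log)


def train_classifier(
    model: ImageClassifier | EmbeddingClassifier,
    inputs: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    warm_start: bool = False,
) -> pd.DataFrame:
    """Train a classifier in place; returns the per-epoch training log.

    A single-class labeled set — possible after a budget-10 cold start —
    degrades to uniform class weights with a warning rather than failing.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labeled set is empty")
    if config.loss != "weighted_cross_entropy":
        raise ValueError("classifiers are trained with weighted cross-entropy")
    if np.unique(labels).size < 2:
        warnings.warn(
            "labeled set contains a single class; using uniform class weights",
            SingleClassWarning,
            stacklevel=2,
        )
        weights = np.ones(2)
    else:
        weights = class_weights(labels)
    return _train(model, inputs, labels, config, weights, warm_start=warm_start)


def train_uncertainty_estimator(
    images: np.ndarray,
    targets: EmbeddingMatrix | np.ndarray,
    config: TrainingConfig = ESTIMATOR_CONFIG,
    dropout_rate: float = 0.5,
) -> tuple[UncertaintyEstimator, pd.DataFrame]:
    """Fit the image -> embedding proxy regressor with MSE loss."""
    target_arr = targets.vectors if isinstance(targets, EmbeddingMatrix) else np.asarray(targets, dtype=float)
    images = np.asarray(images, dtype=float)
    if images.shape[0] != target_arr.shape[0]:
        raise ValueError(
            f"image count ({images.shape[0]}) must equal embedding row count ({target_arr.shape[0]})"
        )
    if config.loss != "mean_squared_error":
        config = replace(config, loss="mean_squared_error")
    model = UncertaintyEstimator(
        image_height=images.shape[1],
        image_width=images.shape[2],
        embedding_dim=target_arr.shape[1],
        dropout_rate=dropout_rate,
    )
    log = _train(model, images, target_arr, config, None)
    return model, log


def predict_proba(model: ImageClassifier | EmbeddingClassifier, inputs: np.ndarray) -> np.ndarray:
    """Deterministic class probabilities (dropout disabled); rows sum to 1."""
    if not model.fitted:
        raise RuntimeError("model must be trained before prediction")
    logits = model.network.forward(model._prepare(inputs), train=False)
    return nn.softmax(logits)
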