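"""The M-mode pneumothorax classifier and its Results interface.

The network is a small binary CNN: six convolution blocks (3×3 kernels,
filter counts doubling 8→256, each followed by ReLU and 2×2 max pooling),
a 36% dropout layer, a flatten, a 214-node fully connected layer (ReLU), a
2-node fully connected layer and a softmax — mapping a ``side``×``side``×3
image to two class probabilities (index 1 = PTX positive). Filter counts
and kernel sizes are configuration, so alternatives are one-line changes.

Two entry styles are provided. The functional pair
:func:`build_model` / :func:`predict` exposes the bare network. The
class-based surface follows the Model/Results convention of statistical
modelling packages: :class:`MmodeClassifier` is constructed from a labeled
image dataset (``from_dataset`` also performs the stratified
train/validation/test split), its :meth:`~MmodeClassifier.fit` runs the
training protocol and returns a :class:`TrainingResults` object carrying
the per-epoch history, the best-epoch weights, held-out evaluation helpers
and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ptxmode import nn

__all__ = [
    "ArchitectureConfig",
    "ConfigurationError",
    "build_model",
    "predict",
    "MmodeClassifier",
    "TrainingResults",
]

DEFAULT_CONV_BLOCKS = ((8, 3), (16, 3), (32, 3), (64, 3), (128, 3), (256, 3))


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape of the 6-block CNN.

    ``input_side`` must be divisible by 2\\ :sup:`6` so that six pooling
    halvings land on an integer spatial size (512 for full-resolution work,
    128 or 64 for desk-scale runs).
    """

    input_side: int = 512
    channels: int = 3
    conv_blocks: tuple[tuple[int, int], ...] = DEFAULT_CONV_BLOCKS
    dropout_rate: float = 0.36
    dense_units: int = 214
    output_units: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 6:
            raise ConfigurationError(
                f"architecture requires exactly 6 conv blocks, got "
                f"{len(self.conv_blocks)}"
            )
        if self.input_side % 64 != 0:
            raise ConfigurationError(
                f"input_side={self.input_side} not divisible by 2^6=64 "
                "(six pooling halvings)"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError(
                f"dropout_rate={self.dropout_rate} outside [0, 1)"
            )
        for f, k in self.conv_blocks:
            if f < 1 or k < 1 or k % 2 == 0:
                raise ConfigurationError(
                    f"conv block (filters={f}, kernel={k}) invalid: filters "
                    ">= 1 and odd kernel required"
                )

    @property
    def flat_side(self) -> int:
        """Spatial side entering the flatten layer (input_side / 2^6)."""
        return self.input_side // 64

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> nn.Network:
    """Instantiate the network with seeded He/Glorot initialization."""
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = cfg.channels
    for filters, kernel in cfg.conv_blocks:
        layers.append(nn.Conv2D(c_in, filters, kernel, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2())
        c_in = filters
    layers.append(nn.Dropout(cfg.dropout_rate))
    layers.append(nn.Flatten())
    flat = cfg.flat_side * cfg.flat_side * c_in
    layers.append(nn.Dense(flat, cfg.dense_units, rng, init="he"))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(cfg.dense_units, cfg.output_units, rng,
                           init="glorot"))
    return nn.Network(layers)


def _as_batch(images: np.ndarray, side: int) -> np.ndarray:
    """Coerce (N,H,W) or (N,H,W,3) input to the NHWC float32 model batch."""
    X = np.asarray(images, dtype=np.float32)
    if X.ndim == 3:
        X = np.repeat(X[..., None], 3, axis=3)
    if X.ndim != 4 or X.shape[3] != 3:
        raise ValueError(f"expected (N,side,side[,3]) images, got {X.shape}")
    if X.shape[1] != side or X.shape[2] != side:
        raise ValueError(
            f"images are {X.shape[1]}x{X.shape[2]} but the model expects "
            f"{side}x{side}"
        )
    return X


def predict(network: nn.Network, images: np.ndarray, input_side: int,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode class probabilities and argmax labels.

    Dropout is off, so repeated calls on the same images are identical.
    """
    X = _as_batch(images, input_side)
    probs = []
    for start in range(0, X.shape[0], batch_size):
        logits = network.forward(X[start:start + batch_size], training=False)
        probs.append(nn.softmax(logits.astype(np.float64)))
    proba = np.concatenate(probs, axis=0)
    return proba, proba.argmax(axis=1)


class MmodeClassifier:
    """Model object: a labeled M-mode segment dataset plus an architecture.

    Parameters
    ----------
    X, y : arrays
        Training images (N, side, side) in [0, 1] and integer labels
        (1 = PTX positive).
    validation, test : optional (X, y) pairs
        Held-out splits. ``from_dataset`` builds all three at once.
    arch : ArchitectureConfig
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 arch: ArchitectureConfig,
                 validation: tuple[np.ndarray, np.ndarray] | None = None,
                 test: tuple[np.ndarray, np.ndarray] | None = None) -> None:
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.arch = arch
        self.validation = validation
        self.test = test

    @classmethod
    def from_dataset(cls, X: np.ndarray, y: np.ndarray,
                     arch: ArchitectureConfig,
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0) -> "MmodeClassifier":
        """Stratified-split a labeled set and build the model around it."""
        from ptxmode.train import split_dataset
        (Xt, yt), (Xv, yv), (Xs, ys) = split_dataset(X, y, fractions, seed)
        return cls(Xt, yt, arch, validation=(Xv, yv), test=(Xs, ys))

    def fit(self, cfg=None, seed: int = 0) -> "TrainingResults":
        """Train with early stopping; returns a :class:`TrainingResults`."""
        from ptxmode.train import TrainConfig, fit as _fit
        if cfg is None:
            cfg = TrainConfig()
        if self.validation is None:
            raise ValueError(
                "fit requires a validation split; use from_dataset or pass "
                "validation=(X, y)"
            )
        network = build_model(self.arch, seed=seed)
        network, history = _fit(network, (self.X, self.y), self.validation,
                                cfg, seed=seed, input_side=self.arch.input_side)
        return TrainingResults(model=self, network=network, history=history,
                               train_config=cfg, seed=seed)


@dataclass
class TrainingResults:
    """Fitted-model results: weights, history, and evaluation helpers."""

    model: MmodeClassifier
    network: nn.Network
    history: pd.DataFrame
    train_config: object
    seed: int

    @property
    def best_epoch(self) -> int:
        return int(self.history["val_loss"].idxmin()) + 1

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return predict(self.network, images, self.model.arch.input_side)

    def evaluate(self, X: np.ndarray | None = None,
                 y: np.ndarray | None = None):
        """Confusion matrix + metrics on (X, y), default the test split."""
        from ptxmode.evaluate import confusion, metrics
        if X is None:
            if self.model.test is None:
                raise ValueError("no test split stored; pass X and y")
            X, y = self.model.test
        _, pred = self.predict(X)
        cm = confusion(np.asarray(y), pred)
        return cm, metrics(cm)

    def summary(self) -> str:
        """A compact fit report in the style of statistical Results objects."""
        arch = self.model.arch
        lines = [
            "M-mode PTX classifier — training results",
            "=" * 48,
            f"parameters:        {self.network.n_parameters:,}",
            f"input:             {arch.input_side}x{arch.input_side}x{arch.channels}",
            f"training images:   {self.model.X.shape[0]}",
            f"epochs run:        {self.n_epochs} (best: {self.best_epoch})",
            f"seed:              {self.seed}",
            f"final train loss:  {self.history['train_loss'].iloc[-1]:.4f}",
            f"best val loss:     {self.history['val_loss'].min():.4f}",
            f"best val accuracy: "
            f"{self.history.loc[self.history['val_loss'].idxmin(), 'val_acc']:.4f}",
        ]
        if self.model.test is not None:
            cm, mets = self.evaluate()
            lines.append(f"test accuracy:     {mets['accuracy']:.4f}"
                         if mets["accuracy"] is not None else
                         "test accuracy:     -")
            lines.append(f"confusion (TP FP / FN TN): "
                         f"{cm.tp} {cm.fp} / {cm.fn} {cm.tn}")
        return "\n".join(lines)
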