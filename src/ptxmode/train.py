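"""Training protocol: stratified splits, early stopping, replicate models.

The protocol is the standard small-CNN recipe: a 70/15/15 stratified
train/validation/test split, Adam at learning rate 0.001, batch size 30,
up to 100 epochs with a validation patience of 5 (training stops once the
validation loss has gone 5 consecutive epochs without strict improvement),
and the weights returned are those of the minimum-validation-loss epoch,
not the final one. Replicate models re-train on the *same* split under
different seeds, isolating seed-driven training variance.

Split sizes use ``floor(fraction * n)`` per class for validation and test,
with the remainder assigned to training (so 10 images per class at
70/15/15 give 8/1/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptxmode import nn
from ptxmode.model import ArchitectureConfig, build_model, _as_batch

__all__ = [
    "TrainConfig",
    "DataError",
    "TrainingDivergence",
    "split_dataset",
    "early_stopping_trace",
    "fit",
    "run_replicates",
]


class DataError(ValueError):
    pass


class TrainingDivergence(RuntimeError):
    """Raised when the loss goes non-finite; names the offending epoch."""


@dataclass(frozen=True)
class TrainConfig:
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 100
    patience: int = 5
    learning_rate: float = 0.001
    batch_size: int = 30
    replicate_seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise DataError(
                f"split fractions {self.split_fractions} do not sum to 1"
            )
        if not 0 < self.patience < self.max_epochs:
            raise DataError(
                f"patience {self.patience} must lie in (0, max_epochs)"
            )
        if len(self.replicate_seeds) < 1:
            raise DataError("at least one replicate seed required")


def split_dataset(X: np.ndarray, y: np.ndarray,
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0):
    """Disjoint, exhaustive, per-class stratified 3-way partition.

    Returns ``((Xtr, ytr), (Xva, yva), (Xte, yte))``. Validation and test
    take ``floor(f * n_class)`` items per class; the remainder trains.
    Reproducible from ``seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError(f"fractions {fractions} do not sum to 1")
    rng = np.random.default_rng(seed)
    idx_tr, idx_va, idx_te = [], [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        n = len(members)
        n_va = int(np.floor(fractions[1] * n))
        n_te = int(np.floor(fractions[2] * n))
        if n - n_va - n_te < 1 or n_va < 1 or n_te < 1:
            raise DataError(
                f"class {cls} has {n} images: not enough for at least one "
                "image per role"
            )
        idx_va.extend(members[:n_va])
        idx_te.extend(members[n_va:n_va + n_te])
        idx_tr.extend(members[n_va + n_te:])
    idx_tr, idx_va, idx_te = map(np.asarray, (idx_tr, idx_va, idx_te))
    return ((X[idx_tr], y[idx_tr]), (X[idx_va], y[idx_va]),
            (X[idx_te], y[idx_te]))


def early_stopping_trace(val_losses, patience: int) -> tuple[int, int]:
    """Apply the patience rule to a sequence of per-epoch validation losses.

    Returns ``(stop_epoch, best_epoch)``, both 1-based. An epoch merely
    *equalling* the best loss does not reset patience — strict improvement
    is required. Training stops after the epoch on which the loss has
    failed to improve for ``patience`` consecutive epochs, or at the end
    of the sequence.
    """
    best = np.inf
    best_epoch = 0
    bad = 0
    for e, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, bad = loss, e, 0
        else:
            bad += 1
            if bad >= patience:
                return e, best_epoch
    return len(val_losses), best_epoch


def _epoch_eval(network: nn.Network, X: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    """Inference-mode mean loss and accuracy over a whole split."""
    losses, correct = [], 0
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        logits = network.forward(xb, training=False)
        loss, _ = nn.cross_entropy_with_grad(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / X.shape[0]), correct / X.shape[0]


def fit(network: nn.Network,
        train: tuple[np.ndarray, np.ndarray],
        validation: tuple[np.ndarray, np.ndarray],
        cfg: TrainConfig, seed: int = 0,
        input_side: int | None = None) -> tuple[nn.Network, pd.DataFrame]:
    """Train with Adam + early stopping; restore best-epoch weights.

    ``history`` has one row per epoch run: train_loss, train_acc, val_loss,
    val_acc. The returned network carries the weights of the epoch with
    minimum validation loss. Deterministic for fixed seed and data.
    """
    Xtr_raw, ytr = train
    Xva_raw, yva = validation
    if len(ytr) == 0 or len(yva) == 0:
        raise DataError("empty training or validation set")
    side = input_side if input_side is not None else Xtr_raw.shape[1]
    Xtr = _as_batch(Xtr_raw, side)
    Xva = _as_batch(Xva_raw, side)
    ytr = np.asarray(ytr, dtype=np.int64)
    yva = np.asarray(yva, dtype=np.int64)

    rng = np.random.default_rng(seed)
    opt = nn.Adam(network, lr=cfg.learning_rate)
    rows = []
    best_loss = np.inf
    best_weights = network.get_weights()
    bad = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(ytr))
        ep_losses, ep_correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            logits = network.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.cross_entropy_with_grad(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite training loss at epoch {epoch}"
                )
            network.backward(dlogits)
            opt.step()
            ep_losses.append(loss * len(yb))
            ep_correct += int((logits.argmax(axis=1) == yb).sum())

        train_loss = float(np.sum(ep_losses) / len(ytr))
        train_acc = ep_correct / len(ytr)
        val_loss, val_acc = _epoch_eval(network, Xva, yva, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingDivergence(
                f"non-finite validation loss at epoch {epoch}"
            )
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "train_acc": train_acc, "val_loss": val_loss,
                     "val_acc": val_acc})

        if val_loss < best_loss:
            best_loss, bad = val_loss, 0
            best_weights = network.get_weights()
        else:
            bad += 1
            if bad >= cfg.patience:
                break

    network.set_weights(best_weights)
    history = pd.DataFrame(rows)
    return network, history


def run_replicates(train: tuple[np.ndarray, np.ndarray],
                   validation: tuple[np.ndarray, np.ndarray],
                   arch: ArchitectureConfig, cfg: TrainConfig):
    """Train one model per replicate seed on a shared split.

    Returns ``(results, errors)``: a list of ``(seed, network, history)``
    for the seeds that trained, and a dict of per-seed exceptions for those
    that failed — a failing replicate never aborts the remaining ones.
    """
    results, errors = [], {}
    for s in cfg.replicate_seeds:
        try:
            network = build_model(arch, seed=s)
            network, history = fit(network, train, validation, cfg, seed=s,
                                   input_side=arch.input_side)
            results.append((s, network, history))
        except Exception as exc:  # noqa: BLE001 - per-seed isolation
            errors[s] = exc
    return results, errors
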