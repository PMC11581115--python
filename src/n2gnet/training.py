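"""Subject-dependent training with early stopping on validation L1.

The loop minimizes mean absolute error with Adam, evaluates the full
validation set after every epoch, and stops once ``patience_epochs`` pass
without a new validation minimum (or at ``max_epochs``). The returned
checkpoint holds the parameters from the best-validation epoch — ties
resolve to the earliest epoch.

Published-scale defaults (lr 1e-5, batch 16, 2000 epochs, patience 100)
are kept as the configuration defaults; desk-scale overrides for quick
experiments live in :mod:`n2gnet.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import N2GNet
from .nn import Adam


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 2000
    patience_epochs: int = 100
    seed: int = 0
    shuffle_each_epoch: bool = True

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.patience_epochs < self.max_epochs:
            raise ValueError("need 0 < patience_epochs < max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    """Per-epoch losses plus the selected checkpoint (epochs are 1-based)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    checkpoint: dict | None = None
    best_val_loss: float = float("inf")


class PatienceTracker:
    """Early-stopping bookkeeping: strict improvement resets the counter."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = float("inf")
        self.best_epoch = 0
        self.epochs_since_improvement = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


def select_best_epoch(val_losses: list[float]) -> int:
    """1-based index of the minimum validation loss (earliest on ties)."""
    if not val_losses:
        raise ValueError("empty history")
    return int(np.argmin(val_losses)) + 1


def _mean_l1(model: N2GNet, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(model.predict(X) - y).mean())


def train(model: N2GNet, train_X: np.ndarray, train_y: np.ndarray,
          val_X: np.ndarray, val_y: np.ndarray,
          cfg: TrainConfig | None = None,
          verbose: bool = False) -> TrainHistory:
    """Fit the network; returns history with the best-epoch checkpoint."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if train_X.shape[0] == 0 or val_X.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(learning_rate=cfg.learning_rate)
    tracker = PatienceTracker(cfg.patience_epochs)
    history = TrainHistory()
    n = train_X.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n) if cfg.shuffle_each_epoch \
            else np.arange(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb, yb = train_X[batch], train_y[batch]
            model.zero_grad()
            pred = model.forward(xb, train=True)
            err = pred - yb
            loss = float(np.abs(err).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate")
            model.backward(np.sign(err) / err.size)
            optimizer.step(model.named_parameters())
            epoch_losses.append(loss)

        val_loss = _mean_l1(model, val_X, val_y)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        if verbose:
            print(f"epoch {epoch:4d}  train L1 {history.train_loss[-1]:.4f}"
                  f"  val L1 {val_loss:.4f}")
        improved = val_loss < tracker.best
        stop = tracker.update(val_loss)
        if improved:
            history.checkpoint = model.state_dict()
            history.best_val_loss = val_loss
        if stop:
            break

    history.best_epoch = tracker.best_epoch
    history.stopped_epoch = tracker.epoch
    return history


def restore_best(model: N2GNet, history: TrainHistory) -> N2GNet:
    """Load the best-validation-epoch parameters back into the model."""
    if history.checkpoint is None:
        raise ValueError("history carries no checkpoint")
    model.load_state_dict(history.checkpoint)
    return model
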