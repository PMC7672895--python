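"""Training configuration and the shared supervised loop with early stopping."""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .ops import cross_entropy

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainingError", "supervised_fit"]


class TrainingError(RuntimeError):
    """Training diverged or received unusable data."""


@dataclass
class TrainConfig:
    """Hyperparameters shared by both stages.

    Defaults follow the training protocol of the method: Adam with learning
    rate 1e-4, mini-batches of 500, dropout 0.5 after hidden layers, and
    early stopping on validation loss.
    """

    learning_rate: float = 1e-4
    batch_size: int = 500
    dropout: float = 0.5
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    cd_steps: int = 1
    pretrain_epochs: int = 5
    val_fraction: float = 0.15
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def supervised_fit(model, X_train, y_train, X_val, y_val,
                   config: TrainConfig, rng: np.random.Generator) -> dict:
    """Mini-batch cross-entropy training with Adam and patience-based stopping.

    ``model`` must expose ``params`` (named dict), ``loss_and_grads`` and
    ``predict_proba``.  The model is left holding the best-validation
    parameters.  Returns the history (per-epoch train/val losses).
    """
    from .ops import Adam

    opt = Adam(lr=config.learning_rate)
    n = len(X_train)
    bs = min(config.batch_size, n)
    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    best_epoch = -1
    wait = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx],
                                               rng=rng, dropout=config.dropout)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = cross_entropy(model.predict_proba(X_val), y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_params = copy.deepcopy(model.params)
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait > config.patience:
                break
    model.params = best_params
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return history
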