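"""Mini-batch training loop with validation-loss early stopping.

The loop restores the weights of the epoch with minimum validation loss,
mirroring the early-stopping protocol used for all deep models in the
pipeline. Determinism: initialization and shuffling derive from explicit
seeds, and all math is single-threaded-deterministic numpy.
"""
from __future__ import annotations

import gc
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import autograd as ag
from .layers import Module
from .optim import Adam

# forward_loss(model, X, Y) -> (loss Tensor, n_correct, n_scored)
ForwardLoss = Callable[[Module, np.ndarray, np.ndarray], tuple]


@dataclass
class History:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "best_epoch": self.best_epoch,
                "best_val_loss": self.best_val_loss}


def _evaluate(model: Module, X: np.ndarray, Y: np.ndarray,
              forward_loss: ForwardLoss, batch_size: int) -> tuple[float, float]:
    model.set_training(False)
    tot_loss = 0.0
    tot_correct = 0
    tot_scored = 0
    with ag.no_grad():
        for start in range(0, len(X), batch_size):
            xb = X[start:start + batch_size]
            yb = Y[start:start + batch_size]
            loss, correct, scored = forward_loss(model, xb, yb)
            tot_loss += float(loss.data) * scored
            tot_correct += correct
            tot_scored += scored
    return tot_loss / max(tot_scored, 1), tot_correct / max(tot_scored, 1)


def fit(model: Module, X: np.ndarray, Y: np.ndarray,
        X_val: np.ndarray, Y_val: np.ndarray, forward_loss: ForwardLoss,
        *, lr: float, batch_size: int, max_epochs: int, patience: int,
        seed: int) -> History:
    if len(X) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history = History()
    best_state = model.state()
    since_best = 0
    for epoch in range(max_epochs):
        model.set_training(True)
        order = rng.permutation(len(X))
        run_loss = 0.0
        run_correct = 0
        run_scored = 0
        for start in range(0, len(X), batch_size):
            idx = order[start:start + batch_size]
            loss, correct, scored = forward_loss(model, X[idx], Y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            run_loss += float(loss.data) * scored
            run_correct += correct
            run_scored += scored
            del loss
        gc.collect()          # break Tensor<->closure reference cycles
        val_loss, val_acc = _evaluate(model, X_val, Y_val, forward_loss, batch_size)
        history.epochs.append({
            "epoch": epoch,
            "train_loss": run_loss / max(run_scored, 1),
            "train_acc": run_correct / max(run_scored, 1),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = model.state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.load_state(best_state)
    model.set_training(False)
    return history


def to_channels_last(xb: np.ndarray) -> np.ndarray:
    """Public (n, C, L) window batches -> internal (n, L, C) layout."""
    return np.ascontiguousarray(np.asarray(xb, dtype=np.float32)
                                .transpose(0, 2, 1))


def classification_loss(model: Module, xb: np.ndarray, yb: np.ndarray) -> tuple:
    """Cross-entropy for window classifiers; yb is one-hot (n, k)."""
    logits = model(ag.Tensor(to_channels_last(xb)))
    loss = ag.softmax_cross_entropy(logits, yb)
    correct = int((logits.data.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return loss, correct, len(xb)


def pointwise_loss(model: Module, xb: np.ndarray, yb: np.ndarray) -> tuple:
    """Per-time-point cross-entropy; yb is one-hot (n, L, k)."""
    logits = model(ag.Tensor(to_channels_last(xb)))     # (n, L, k)
    n, L, k = logits.shape
    flat = logits.reshape(n * L, k)
    onehot = yb.reshape(n * L, k)
    loss = ag.softmax_cross_entropy(flat, onehot)
    correct = int((flat.data.argmax(axis=1) == onehot.argmax(axis=1)).sum())
    return loss, correct, n * L
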