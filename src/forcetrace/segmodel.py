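"""Point-wise ON/OFF segmentation of force recordings.

A 1-D U-Net variant (convolutional encoder-decoder with skip
connections) classifies every sample of a standardized two-channel force
window as tool-active (ON) or idle (OFF). Post-processing turns the
per-sample probabilities into continuous force-ON blocks: thresholding,
reconciliation of short noise-driven discontinuities (gap merging), and a
minimum-length requirement.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from ._nn import autograd as ag
from ._nn.autograd import Tensor
from ._nn.layers import Conv1d, ConvBlock, Module
from ._nn.training import History, fit, pointwise_loss, to_channels_last
from .core import ForceRecording

CLASSES = ("OFF", "ON")      # column order of the softmax head


@dataclass
class TUNetConfig:
    window: int = 224
    in_channels: int = 2
    base_filters: int = 16
    depth: int = 3                 # number of 2x poolings
    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.window % (2 ** self.depth) != 0:
            raise ValueError(
                f"window {self.window} not divisible by 2^{self.depth}")


class TUNet(Module):
    """1-D encoder-decoder with skip connections and a per-point softmax."""

    def __init__(self, cfg: TUNetConfig):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        f = cfg.base_filters
        c_in = cfg.in_channels
        self.enc = []
        for level in range(cfg.depth):
            self.enc.append([ConvBlock(c_in, f, 3, rng),
                             ConvBlock(f, f, 3, rng)])
            c_in = f
            f *= 2
        self.bottom = [ConvBlock(c_in, f, 3, rng), ConvBlock(f, f, 3, rng)]
        self.dec = []
        for level in range(cfg.depth):
            up_out = f // 2
            self.dec.append({
                "up": Conv1d(f, up_out, 3, rng),
                "blocks": [ConvBlock(up_out * 2, up_out, 3, rng),
                           ConvBlock(up_out, up_out, 3, rng)],
            })
            f = up_out
        self.head = Conv1d(f, len(CLASSES), 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(n, L, C) standardized windows -> (n, L, 2) point logits."""
        skips = []
        for blocks in self.enc:
            for blk in blocks:
                x = blk(x)
            skips.append(x)
            x = ag.maxpool2(x)
        for blk in self.bottom:
            x = blk(x)
        for level, dec in enumerate(self.dec):
            x = dec["up"](ag.upsample2(x))
            x = ag.concat([skips[-(level + 1)], x], axis=2)
            for blk in dec["blocks"]:
                x = blk(x)
        return self.head(x)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """ON probability per sample from (n, 2, L) windows; shape (n, L)."""
        self.set_training(False)
        on_col = CLASSES.index("ON")
        out = []
        with ag.no_grad():
            for start in range(0, len(windows), self.cfg.batch_size):
                xb = to_channels_last(windows[start:start + self.cfg.batch_size])
                probs = ag.softmax(self(Tensor(xb)).data, axis=2)
                out.append(probs[:, :, on_col])
        return np.concatenate(out) if out else np.zeros((0, windows.shape[-1]))


def build_tunet(cfg: TUNetConfig) -> TUNet:
    return TUNet(cfg)


def _onehot_points(labels: np.ndarray) -> np.ndarray:
    """(n, L) boolean ON mask -> (n, L, 2) one-hot in CLASSES order."""
    on = labels.astype(np.float32)
    return np.stack([1.0 - on, on], axis=-1)


def train_segmenter(model: TUNet, train: tuple, val: tuple,
                    cfg: TUNetConfig | None = None) -> History:
    """Train on ``(windows, point_labels)`` pairs with early stopping.

    Point labels are boolean ON masks of shape (n, L); loss is per-point
    cross-entropy, and the minimum-validation-loss weights are restored.
    """
    cfg = model.cfg if cfg is None else cfg
    X, y = train
    Xv, yv = val
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("empty training or validation batch")
    return fit(model, np.asarray(X, dtype=np.float32), _onehot_points(np.asarray(y)),
               np.asarray(Xv, dtype=np.float32), _onehot_points(np.asarray(yv)),
               pointwise_loss, lr=cfg.learning_rate, batch_size=cfg.batch_size,
               max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed)


def grid_search(base_cfg: TUNetConfig, space: dict[str, list], train: tuple,
                val: tuple) -> tuple[TUNetConfig, list[dict]]:
    """Exhaustive hyperparameter search selecting minimum validation loss.

    ``space`` maps config field names to candidate values; returns the
    winning config and a leaderboard sorted by validation loss.
    """
    names = list(space)
    leaderboard = []
    for combo in itertools.product(*(space[n] for n in names)):
        cfg = replace(base_cfg, **dict(zip(names, combo)))
        model = build_tunet(cfg)
        history = train_segmenter(model, train, val, cfg)
        leaderboard.append({**dict(zip(names, combo)),
                            "val_loss": history.best_val_loss,
                            "best_epoch": history.best_epoch})
    leaderboard.sort(key=lambda row: row["val_loss"])
    best = replace(base_cfg, **{n: leaderboard[0][n] for n in names})
    return best, leaderboard


def predict_pointwise(model: TUNet, recording: ForceRecording) -> np.ndarray:
    """Per-sample ON probability for a (standardized) recording.

    The recording is tiled into non-overlapping windows; a final partial
    window is edge-padded for inference and its padding predictions are
    discarded, so the output length equals the recording length.
    """
    L = model.cfg.window
    data = recording.channels().astype(np.float32)
    n = data.shape[1]
    n_full = n // L
    windows = []
    for i in range(n_full):
        windows.append(data[:, i * L:(i + 1) * L])
    rem = n - n_full * L
    if rem:
        tail = np.pad(data[:, n_full * L:], ((0, 0), (0, L - rem)), mode="edge")
        windows.append(tail)
    probs = model.predict_proba(np.stack(windows))
    flat = probs.reshape(-1)
    return flat[:n]


def extract_segments(probabilities: np.ndarray, threshold: float = 0.5,
                     min_len: int = 40, gap_tol: int = 10,
                     ) -> list[tuple[int, int]]:
    """Continuous force-ON blocks from per-sample ON probabilities.

    Binarize at ``threshold``, merge ON runs separated by OFF gaps of at
    most ``gap_tol`` samples (reconciling noise-driven discontinuities),
    then drop merged runs shorter than ``min_len``. Returns sorted,
    disjoint half-open ``(start, end)`` index pairs.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.size and (probabilities.min() < 0 or probabilities.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    mask = probabilities >= threshold
    runs = _runs(mask)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= gap_tol:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e - s >= min_len]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
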