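"""Skill and task recognition models for force-ON segments.

The primary classifier is an InceptionTime-style convolutional network
over fixed-length force windows ("FTFIT"): stacked inception modules
(bottleneck 1-wide convolution feeding three parallel convolutions of
different kernel widths plus a max-pool branch), a residual shortcut
every third module, global average pooling and a softmax head. Input
windows carry the two prong channels and optionally a third channel
encoding hand-crafted segment features. An LSTM classifier and an
XGBoost model on engineered features serve as baselines, and a logistic
head can combine the pooled FTFIT embedding with engineered features.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from ._nn import autograd as ag
from ._nn.autograd import Tensor
from ._nn.layers import BatchNorm1d, Conv1d, Dense, LSTM, Module, global_avg_pool
from ._nn.training import History, classification_loss, fit, to_channels_last


@dataclass
class FTFITConfig:
    window: int = 200
    in_channels: int = 2
    depth: int = 6                       # inception modules (12 for task runs)
    bottleneck: int = 32                 # width of every branch
    kernel_sizes: tuple[int, ...] = (10, 20, 40)
    residual_every: int = 3
    n_classes: int = 2
    learning_rate: float = 0.001         # 0.01 for the full-scale task run
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if any(k >= self.window for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be smaller than the window")


@dataclass
class LSTMConfig:
    window: int = 200
    in_channels: int = 2
    hidden: int = 64
    layers: int = 2
    n_classes: int = 2
    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0


class InceptionModule(Module):
    def __init__(self, c_in: int, width: int, kernels: tuple[int, ...],
                 rng: np.random.Generator):
        self.bottleneck = Conv1d(c_in, width, 1, rng)
        self.branches = [Conv1d(width, width, k, rng) for k in kernels]
        self.pool_conv = Conv1d(c_in, width, 1, rng)
        self.bn = BatchNorm1d(width * (len(kernels) + 1))

    def __call__(self, x: Tensor) -> Tensor:
        z = self.bottleneck(x)
        parts = [branch(z) for branch in self.branches]
        parts.append(self.pool_conv(ag.maxpool3_same(x)))
        return self.bn(ag.concat(parts, axis=2)).relu()


class FTFIT(Module):
    """Inception-module stack with periodic residual shortcuts."""

    def __init__(self, cfg: FTFITConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        width = cfg.bottleneck
        self.out_channels = width * (len(cfg.kernel_sizes) + 1)
        self.blocks = []
        self.shortcuts = []
        c_in = cfg.in_channels
        res_in = cfg.in_channels
        for d in range(cfg.depth):
            self.blocks.append(InceptionModule(c_in, width, cfg.kernel_sizes,
                                               rng))
            c_in = self.out_channels
            if (d + 1) % cfg.residual_every == 0:
                self.shortcuts.append({
                    "after": d,
                    "conv": Conv1d(res_in, self.out_channels, 1, rng),
                    "bn": BatchNorm1d(self.out_channels),
                })
                res_in = self.out_channels
        self.head = Dense(self.out_channels, cfg.n_classes, rng)

    def _forward_pooled(self, x: Tensor) -> Tensor:
        shortcuts = {s["after"]: s for s in self.shortcuts}
        res = x
        for d, block in enumerate(self.blocks):
            x = block(x)
            if d in shortcuts:
                s = shortcuts[d]
                x = (x + s["bn"](s["conv"](res))).relu()
                res = x
        return global_avg_pool(x)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self._forward_pooled(x))

    def embed(self, windows: np.ndarray) -> np.ndarray:
        """Pooled embedding (n, 4 * bottleneck) from (n, C, L) windows."""
        self.set_training(False)
        out = []
        with ag.no_grad():
            for i in range(0, len(windows), self.cfg.batch_size):
                xb = to_channels_last(windows[i:i + self.cfg.batch_size])
                out.append(self._forward_pooled(Tensor(xb)).data)
        return np.concatenate(out)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        self.set_training(False)
        out = []
        with ag.no_grad():
            for i in range(0, len(windows), self.cfg.batch_size):
                xb = to_channels_last(windows[i:i + self.cfg.batch_size])
                out.append(ag.softmax(self(Tensor(xb)).data, axis=1))
        return np.concatenate(out)


class LSTMClassifier(Module):
    """Stacked LSTM over force windows, softmax on the final state."""

    def __init__(self, cfg: LSTMConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.in_channels] + [cfg.hidden] * cfg.layers
        self.cells = [LSTM(dims[i], dims[i + 1], rng)
                      for i in range(cfg.layers)]
        self.head = Dense(cfg.hidden, cfg.n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        hs = self.cells[0](x)
        for cell in self.cells[1:]:
            # stack the h sequence back into (n, L, H) for the next layer
            seq = ag.concat([h.reshape(h.shape[0], 1, h.shape[1]) for h in hs],
                            axis=1)
            hs = cell(seq)
        return self.head(hs[-1])

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        self.set_training(False)
        out = []
        with ag.no_grad():
            for i in range(0, len(windows), self.cfg.batch_size):
                xb = to_channels_last(windows[i:i + self.cfg.batch_size])
                out.append(ag.softmax(self(Tensor(xb)).data, axis=1))
        return np.concatenate(out)


def build_ftfit(cfg: FTFITConfig) -> FTFIT:
    return FTFIT(cfg)


def build_lstm(cfg: LSTMConfig) -> LSTMClassifier:
    return LSTMClassifier(cfg)


def train_classifier(model, train: tuple, val: tuple, cfg=None) -> History:
    """Train a window classifier with early stopping on validation loss.

    ``train``/``val`` are ``(windows, onehot_labels)`` pairs. Raises if a
    class is absent from the training labels.
    """
    cfg = model.cfg if cfg is None else cfg
    X, y = train
    Xv, yv = val
    y = np.asarray(y, dtype=np.float32)
    if y.ndim != 2:
        raise ValueError("labels must be one-hot encoded")
    if (y.sum(axis=0) == 0).any():
        missing = int(np.argmax(y.sum(axis=0) == 0))
        raise ValueError(f"class {missing} missing from the training set")
    return fit(model, np.asarray(X, dtype=np.float32), y,
               np.asarray(Xv, dtype=np.float32),
               np.asarray(yv, dtype=np.float32),
               classification_loss, lr=cfg.learning_rate,
               batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
               patience=cfg.patience, seed=cfg.seed)


def train_xgb_baseline(X: pd.DataFrame | np.ndarray, y, seed: int = 0,
                       ) -> XGBClassifier:
    """Gradient-boosted trees on the engineered features only.

    Labels are encoded in sorted order; the mapping is stored on the
    returned model as ``label_classes_``.
    """
    classes, codes = np.unique(np.asarray(y), return_inverse=True)
    model = XGBClassifier(n_estimators=200, max_depth=4, learning_rate=0.1,
                          random_state=seed, verbosity=0)
    model.fit(np.asarray(X, dtype=float), codes)
    model.label_classes_ = classes
    return model


@dataclass
class HybridLogistic:
    """Logistic regression on [FTFIT embedding | standardized features]."""

    ftfit: FTFIT
    clf: LogisticRegression = field(default=None)
    feat_mean: np.ndarray = field(default=None)
    feat_sd: np.ndarray = field(default=None)

    def _design(self, windows: np.ndarray, feats: np.ndarray) -> np.ndarray:
        emb = self.ftfit.embed(np.asarray(windows, dtype=np.float32))
        fs = (np.asarray(feats, dtype=float) - self.feat_mean) / self.feat_sd
        return np.column_stack([emb, fs])

    def fit(self, windows: np.ndarray, feats: np.ndarray, y) -> "HybridLogistic":
        feats = np.asarray(feats, dtype=float)
        if len(windows) != len(feats) or len(feats) != len(y):
            raise ValueError("windows, features and labels must align")
        self.feat_mean = feats.mean(axis=0)
        self.feat_sd = np.where(feats.std(axis=0) == 0, 1.0, feats.std(axis=0))
        self.label_classes_, codes = np.unique(np.asarray(y),
                                               return_inverse=True)
        self.clf = LogisticRegression(max_iter=2000)
        self.clf.fit(self._design(windows, feats), codes)
        return self

    def predict_proba(self, windows: np.ndarray, feats: np.ndarray) -> np.ndarray:
        if self.clf is None:
            n = len(windows)
            return np.full((n, 2), 0.5)
        return self.clf.predict_proba(self._design(windows, feats))


def hybrid_logistic(ftfit: FTFIT, windows: np.ndarray, feats: np.ndarray,
                    y) -> HybridLogistic:
    """Fit the hybrid learned+engineered logistic classifier."""
    return HybridLogistic(ftfit=ftfit).fit(windows, feats, y)
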