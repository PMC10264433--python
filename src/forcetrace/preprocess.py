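"""Standardization, windowing, balancing, encoding and splitting.

All statistics used to transform data (channel means/SDs, feature
scalings) are fitted on the training partition only; validation and test
data are transformed with the frozen training statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .core import ForceRecording, ForceSegment


@dataclass
class Standardizer:
    """Per-channel zero-mean unit-variance scaling (population SD)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray) -> "Standardizer":
        """Fit on (channels, n) training data."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("need a (channels, n) array with n >= 2")
        mean = data.mean(axis=1)
        sd = data.std(axis=1)
        if np.any(sd <= 0):
            ch = int(np.argmax(sd <= 0))
            raise ValueError(f"zero-variance channel {ch}: cannot standardize")
        return cls(mean=mean, sd=sd)

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        return (data - self.mean[:, None]) / self.sd[:, None]

    def transform_recording(self, rec: ForceRecording) -> ForceRecording:
        out = self.transform(rec.channels())
        return ForceRecording(left=out[0], right=out[1], fs=rec.fs,
                              labels=rec.labels)


def fit_standardizer(recordings: list[ForceRecording]) -> Standardizer:
    data = np.concatenate([rec.channels() for rec in recordings], axis=1)
    return Standardizer.fit(data)


def make_windows(recording: ForceRecording, L: int, stride: int | None = None,
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Cut a recording into (n, 2, L) windows with per-sample labels.

    Windows start at offsets 0, stride, 2*stride, ...; a trailing partial
    window is dropped. Returns ``(windows, point_labels)`` with labels of
    shape (n, L) (or None when the recording is unlabeled).
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    stride = L if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(recording)
    if n < L:
        raise ValueError(f"recording length {n} is shorter than window {L}")
    starts = np.arange(0, n - L + 1, stride)
    data = recording.channels()
    windows = np.stack([data[:, s:s + L] for s in starts])
    labels = None
    if recording.labels is not None:
        labels = np.stack([recording.labels[s:s + L] for s in starts])
    return windows, labels


def balance_idle(recording: ForceRecording, max_off_run: int = 224,
                 ) -> ForceRecording:
    """Trim every maximal OFF run longer than ``max_off_run`` samples.

    Runs are trimmed centrally so the ON-boundary context on both sides
    of each active block is preserved; ON samples are never removed and
    segment order is unchanged. This is the rule-based idle-period data
    balancing applied before training the segmenter.
    """
    if recording.labels is None:
        raise ValueError("balance_idle requires point labels")
    labels = recording.labels
    keep = np.ones(len(labels), dtype=bool)
    n = len(labels)
    i = 0
    while i < n:
        if not labels[i]:
            j = i
            while j < n and not labels[j]:
                j += 1
            run = j - i
            if run > max_off_run:
                head = max_off_run // 2
                tail = max_off_run - head
                keep[i + head:j - tail] = False
            i = j
        else:
            i += 1
    return ForceRecording(left=recording.left[keep],
                          right=recording.right[keep],
                          fs=recording.fs, labels=labels[keep])


def split_nested(items, seed: int) -> tuple[list, list, list]:
    """Random 64/16/20% train/validation/test partition.

    Implemented as the nested 80/20 split: 20% of all items are held out
    for testing, then 20% of the remainder for validation.
    """
    n = len(items)
    if n < 5:
        raise ValueError("need at least 5 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(0.2 * n))
    n_val = int(round(0.2 * (n - n_test)))
    test_idx = order[:n_test]
    val_idx = order[n_test:n_test + n_val]
    train_idx = order[n_test + n_val:]
    pick = lambda idx: [items[i] for i in sorted(idx)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def subsample_class(segments: list[ForceSegment], label: str, fraction: float,
                    seed: int) -> list[ForceSegment]:
    """Randomly keep ``floor(fraction * count)`` members of one task class.

    Other classes are untouched; original ordering is preserved. This is
    the class-balancing step applied to the over-represented Coagulation
    task before task-recognition training.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    members = [i for i, s in enumerate(segments) if s.task == label]
    if not members:
        raise ValueError(f"label {label!r} not present in the data")
    if fraction == 1.0:
        return list(segments)
    rng = np.random.default_rng(seed)
    n_keep = int(np.floor(fraction * len(members)))
    kept = set(rng.choice(members, size=n_keep, replace=False).tolist())
    return [s for i, s in enumerate(segments)
            if s.task != label or i in kept]


def segment_to_window(segment: ForceSegment, L: int = 200) -> np.ndarray:
    """Fixed-length (2, L) window from a segment.

    Longer segments are center-cropped; shorter ones edge-padded by
    repeating the boundary values.
    """
    if len(segment) < 20:
        raise ValueError("segment too short (need >= 20 samples)")
    data = segment.channels()
    n = data.shape[1]
    if n == L:
        return data.copy()
    if n > L:
        start = (n - L) // 2
        return data[:, start:start + L].copy()
    pad_left = (L - n) // 2
    pad_right = L - n - pad_left
    return np.pad(data, ((0, 0), (pad_left, pad_right)), mode="edge")


def feature_channel(values: np.ndarray, L: int = 200, order: int = 3,
                    ) -> np.ndarray:
    """Spread K scalar feature values into a length-L signal channel.

    The K values are placed at equally spaced abscissae spanning the
    window and interpolated with a spline of the given order (0 = step,
    1 = linear, 3 = cubic default); evaluation never leaves the data
    range so boundaries take the edge values. The result is appended to
    the two force channels as a third input signal.
    """
    values = np.asarray(values, dtype=float).ravel()
    K = len(values)
    if K < 1:
        raise ValueError("need at least one feature value")
    if K > L:
        raise ValueError(f"more feature values ({K}) than window samples ({L})")
    if K == 1:
        return np.full(L, values[0])
    x = np.linspace(0, L - 1, K)
    k = int(min(order, K - 1))
    xq = np.arange(L, dtype=float)
    if k == 0:
        idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, K - 1)
        return values[idx]
    spline = make_interp_spline(x, values, k=k)
    return np.asarray(spline(xq))


def one_hot(labels, vocabulary: tuple | list) -> np.ndarray:
    """Encode labels as a (n, len(vocabulary)) one-hot matrix."""
    index = {v: i for i, v in enumerate(vocabulary)}
    out = np.zeros((len(labels), len(vocabulary)), dtype=np.float32)
    for row, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in vocabulary {vocabulary}")
        out[row, index[lab]] = 1.0
    return out
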