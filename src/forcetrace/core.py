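"""Core in-memory containers for force recordings and segments.

A recording is a two-channel (left/right prong) tip-force trace sampled at
a fixed rate (20 Hz on the sensorized bipolar forceps), optionally carrying
a point-wise ON/OFF ground-truth label. A segment is one contiguous
force-ON block cut from a recording, tagged with a surgical task, a skill
level and a surgeon id. Index conventions are 0-based and half-open
[start, end) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TASKS = ("Coagulation", "Manipulating", "Pulling", "Retracting", "Dissecting")
SKILLS = ("Expert", "Novice")
ON, OFF = "ON", "OFF"


@dataclass
class ForceRecording:
    """Two-channel force trace at a fixed sampling rate.

    Attributes
    ----------
    left, right : float arrays (newtons), equal length
    fs : sampling rate in Hz
    labels : optional per-sample ON/OFF mask (boolean, True = ON)
    """

    left: np.ndarray
    right: np.ndarray
    fs: float = 20.0
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=np.float64)
        self.right = np.asarray(self.right, dtype=np.float64)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape != self.left.shape:
                raise ValueError("labels must align with the force channels")

    def __len__(self) -> int:
        return len(self.left)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def channels(self) -> np.ndarray:
        """(2, n) array, row 0 = left prong."""
        return np.stack([self.left, self.right])


@dataclass
class ForceSegment:
    """One contiguous force-ON block with its annotations."""

    left: np.ndarray
    right: np.ndarray
    task: str
    skill: str
    surgeon_id: str
    fs: float = 20.0
    segment_id: int = 0
    start: int = 0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=np.float64)
        self.right = np.asarray(self.right, dtype=np.float64)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.skill not in SKILLS:
            raise ValueError(f"unknown skill {self.skill!r}")

    def __len__(self) -> int:
        return len(self.left)

    @property
    def end(self) -> int:
        return self.start + len(self)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def channels(self) -> np.ndarray:
        return np.stack([self.left, self.right])

    def mean_force(self) -> np.ndarray:
        """Mean of the two prongs, the representative single channel."""
        return 0.5 * (self.left + self.right)


@dataclass
class GroundTruth:
    """Point labels plus the segment annotation table of one recording."""

    point_labels: np.ndarray                     # bool, True = ON
    segments: list[ForceSegment] = field(default_factory=list)

    def __post_init__(self):
        self.point_labels = np.asarray(self.point_labels, dtype=bool)
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for seg in self.segments:
            if seg.start >= seg.end:
                raise ValueError("segment must satisfy start < end")
            if seg.start <= prev_end - 1 or seg.start < prev_end:
                raise ValueError("segments must be sorted and disjoint")
            if seg.end > len(self.point_labels):
                raise ValueError("segment exceeds recording length")
            if not self.point_labels[seg.start:seg.end].all():
                raise ValueError("in-segment points must be labeled ON")
            prev_end = seg.end
        mask = np.zeros(len(self.point_labels), dtype=bool)
        for seg in self.segments:
            mask[seg.start:seg.end] = True
        if (self.point_labels & ~mask).any():
            raise ValueError("out-of-segment points must be labeled OFF")
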