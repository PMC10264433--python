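"""Shared fixtures: small seeded synthetic datasets and helpers."""
from __future__ import annotations

import numpy as np
import pytest

from forcetrace import synth
from forcetrace.core import ForceSegment


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig()


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """300 labeled segments with default generator settings."""
    segments, manifest = synth.generate_dataset(default_config, 300, seed=123)
    return segments, manifest


@pytest.fixture(scope="session")
def random_segments():
    """100 random-noise segments for brute-force feature oracles."""
    rng = np.random.default_rng(99)
    segs = []
    for i in range(100):
        n = int(rng.integers(40, 400))
        left = np.abs(rng.normal(1.0, 0.4, size=n))
        right = np.abs(left + rng.normal(0.0, 0.2, size=n))
        segs.append(ForceSegment(left=left, right=right, task="Coagulation",
                                 skill="Expert", surgeon_id="E01",
                                 segment_id=i))
    return segs


def numerical_gradient(build_loss, arr: np.ndarray, eps: float = 3e-2,
                       ) -> np.ndarray:
    """Central-difference gradient of a scalar loss w.r.t. ``arr``."""
    grad = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = float(build_loss().data)
        arr[idx] = orig - eps
        fm = float(build_loss().data)
        arr[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a.ravel()), np.linalg.norm(b.ravel())
    if na == 0 and nb == 0:
        return 1.0
    return float(np.dot(a.ravel(), b.ravel()) / (na * nb + 1e-12))
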