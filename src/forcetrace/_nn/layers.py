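"""Layer primitives built on the autograd engine."""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state snapshots."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            params.extend(_collect(v))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            for item in _iter_children(v):
                mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m._training = flag

    @property
    def training(self) -> bool:
        return getattr(self, "_training", True)

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameters and buffers (for best-epoch restore)."""
        arrs = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            for buf in getattr(m, "_buffers", ()):
                arrs.append(getattr(m, buf).copy())
        return arrs

    def load_state(self, arrs: list[np.ndarray]) -> None:
        it = iter(arrs)
        for p in self.parameters():
            p.data = next(it).copy()
        for m in self.modules():
            for buf in getattr(m, "_buffers", ()):
                setattr(m, buf, next(it).copy())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _iter_children(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _iter_children(item)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel
        self.w = _param(rng, (c_out, c_in, kernel), np.sqrt(2.0 / fan_in))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _param(rng, (d_in, d_out), np.sqrt(2.0 / d_in))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class BatchNorm1d(Module):
    """Per-channel normalization of (N, L, C) activations with running stats."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, 1, channels)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, 1, channels)), requires_grad=True)
        self.running_mean = np.zeros((1, 1, channels), dtype=np.float32)
        self.running_var = np.ones((1, 1, channels), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batchnorm(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.astype(np.float32))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.astype(np.float32))
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma * Tensor(inv)
        return scale * (x - Tensor(self.running_mean)) + self.beta


class ConvBlock(Module):
    """conv(k) -> batch norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(c_in, c_out, kernel, rng)
        self.bn = BatchNorm1d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class LSTM(Module):
    """Single LSTM layer over (N, L, C) input; returns the h sequence."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        self.wx = _param(rng, (d_in, 4 * hidden), scale)
        self.wh = _param(rng, (hidden, 4 * hidden), scale)
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden:2 * hidden] = 1.0          # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> list[Tensor]:
        n, length, _ = x.shape
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        hs: list[Tensor] = []
        hd = self.hidden
        for t in range(length):
            gates = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = gates[:, :hd].sigmoid()
            f = gates[:, hd:2 * hd].sigmoid()
            g = gates[:, 2 * hd:3 * hd].tanh()
            o = gates[:, 3 * hd:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, L, C) -> (N, C)."""
    return x.mean(axis=1)
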