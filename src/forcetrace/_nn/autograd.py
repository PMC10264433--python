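"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the force-model architectures need:
broadcasting arithmetic, matrix product, 1-D convolution (im2col + GEMM),
max pooling, nearest-neighbour upsampling, concatenation, slicing, the
usual pointwise nonlinearities and a fused softmax cross-entropy loss.
Everything is float32. The graph is walked iteratively (no recursion) so
long recurrent chains are safe.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Callable[[], None] | None = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                # free this node's own gradient and closure: only leaf
                # tensors (parameters/inputs) need grads after backward
                node.grad = None
                node._backward = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            def bw():
                self._accumulate(-out.grad)
            out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad * p * self.data ** (p - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)
            out._backward = bw
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw():
                g = out.grad
                if not keepdims and axis is not None:
                    axes = (axis,) if isinstance(axis, int) else tuple(axis)
                    axes = tuple(a % self.data.ndim for a in axes)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad.reshape(self.shape))
            out._backward = bw
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(*axes), (self,))
        if out._parents:
            inv = np.argsort(axes)
            def bw():
                self._accumulate(out.grad.transpose(*inv))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bw():
                g = np.zeros_like(self.data)
                g[idx] = out.grad
                self._accumulate(g)
            out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad * mask)
            out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad * s * (1.0 - s))
            out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _make(t, (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad * (1.0 - t * t))
            out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad * e)
            out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            def bw():
                self._accumulate(out.grad / self.data)
            out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


# -- structural ops -------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(g)
        out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-length 1-D convolution, channels-last (N, L, C) layout.

    The weight keeps the conventional (out, in, k) shape. Even kernel
    widths use asymmetric ((k-1)//2, k//2) padding. Channels-last makes
    the im2col buffer a near-sequential overlapping copy (the receptive
    field of consecutive output points shares memory), which matters on
    bandwidth-limited hardware; the buffer is cached for the backward
    GEMMs.
    """
    N, L, C = x.data.shape
    O, _, K = w.data.shape
    if K == 1:          # pointwise convolution: a plain per-sample GEMM
        wm = w.data[:, :, 0]                                # (O, C)
        flat = x.data.reshape(N * L, C)
        out = _make((flat @ wm.T).reshape(N, L, O) + b.data, (x, w, b))
        if out._parents:
            def bw1():
                g2 = out.grad.reshape(N * L, O)
                if w.requires_grad:
                    w._accumulate((g2.T @ flat)[:, :, None])
                if b.requires_grad:
                    b._accumulate(out.grad.sum(axis=(0, 1)))
                if x.requires_grad:
                    x._accumulate((g2 @ wm).reshape(N, L, C))
            out._backward = bw1
        return out
    pl, pr = (K - 1) // 2, K // 2
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # shift-and-GEMM: one batched matmul per kernel tap; the padded input
    # stays cache-resident instead of being expanded K-fold by im2col
    acc = xp[:, 0:L, :] @ w.data[:, :, 0].T
    for k in range(1, K):
        acc += xp[:, k:k + L, :] @ w.data[:, :, k].T
    out = _make(acc + b.data, (x, w, b))
    if out._parents:
        def bw():
            g = out.grad
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1)))
            dxp = np.zeros_like(xp) if x.requires_grad else None
            for k in range(K):
                sl = xp[:, k:k + L, :]
                if w.requires_grad:
                    dwk = np.matmul(sl.transpose(0, 2, 1), g).sum(axis=0)
                    w.grad = np.zeros_like(w.data) if w.grad is None else w.grad
                    w.grad[:, :, k] += dwk.T
                if dxp is not None:
                    dxp[:, k:k + L, :] += g @ w.data[:, :, k]
            if dxp is not None:
                x._accumulate(dxp[:, pl:pl + L, :])
        out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """Max pooling with kernel 2, stride 2 along the length axis."""
    N, L, C = x.data.shape
    if L % 2:
        raise ValueError("maxpool2 requires an even length")
    xr = x.data.reshape(N, L // 2, 2, C)
    idx = xr.argmax(axis=2)
    out = _make(np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :],
                (x,))
    if out._parents:
        def bw():
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, idx[:, :, None, :], out.grad[:, :, None, :],
                              axis=2)
            x._accumulate(dxr.reshape(N, L, C))
        out._backward = bw
    return out


def maxpool3_same(x: Tensor) -> Tensor:
    """Max pooling with kernel 3, stride 1, same length (edge padded).

    Computed as an elementwise maximum of three shifted views; gradients
    route to the first (leftmost) argmax on ties, matching ``argmax``.
    """
    N, L, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (0, 0)), constant_values=-np.inf)
    shifts = (xp[:, :L], xp[:, 1:1 + L], xp[:, 2:2 + L])
    out = _make(np.maximum(shifts[0], np.maximum(shifts[1], shifts[2])), (x,))
    if out._parents:
        def bw():
            dxp = np.zeros_like(xp)
            taken = np.zeros(out.data.shape, dtype=bool)
            for k in range(3):
                hit = (shifts[k] == out.data) & ~taken
                dxp[:, k:k + L, :] += np.where(hit, out.grad, 0.0)
                taken |= hit
            x._accumulate(dxp[:, 1:1 + L, :])
        out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
              ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over axes (0, 1).

    Returns ``(out, batch_mean, batch_var)``; the caller maintains the
    running statistics. Fusing keeps the intermediate count (and hence
    memory traffic) far below the op-by-op composition.
    """
    mu = x.data.mean(axis=(0, 1), keepdims=True)
    var = x.data.var(axis=(0, 1), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(gamma.data * xhat + beta.data, (x, gamma, beta))
    if out._parents:
        m = x.data.shape[0] * x.data.shape[1]
        def bw():
            dy = out.grad
            dxhat_sum = (dy * xhat).sum(axis=(0, 1), keepdims=True)
            if beta.requires_grad:
                beta._accumulate(dy.sum(axis=(0, 1), keepdims=True))
            if gamma.requires_grad:
                gamma._accumulate(dxhat_sum)
            if x.requires_grad:
                dx = (gamma.data * inv) * (
                    dy - dy.mean(axis=(0, 1), keepdims=True)
                    - xhat * (dxhat_sum / m))
                x._accumulate(dx)
        out._backward = bw
    return out, mu, var


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 along the length axis."""
    N, L, C = x.data.shape
    out = _make(np.repeat(x.data, 2, axis=1), (x,))
    if out._parents:
        def bw():
            x._accumulate(out.grad.reshape(N, L, 2, C).sum(axis=2))
        out._backward = bw
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows of a (n, k) logit matrix."""
    n = logits.data.shape[0]
    p = softmax(logits.data, axis=1)
    eps = 1e-12
    loss = -(onehot * np.log(p + eps)).sum() / n
    out = _make(np.float32(loss), (logits,))
    if out._parents:
        def bw():
            logits._accumulate((p - onehot) * (out.grad / n))
        out._backward = bw
    return out
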