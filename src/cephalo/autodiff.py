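"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tape` records one backward closure per primitive op during the
forward pass; :meth:`Tape.backward` replays them in reverse.  Only the ops
needed by the convolutional backbone and the MLP refiner are provided
(convolution, batch norm, ReLU, nearest-neighbour upsampling, channel
concatenation, addition, affine layers, sum-of-squares loss).

Everything is float64 and fully deterministic.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np


class Var:
    """A value in the computation graph with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


class Tape:
    """Records backward closures for one forward pass."""

    __slots__ = ("ops",)

    def __init__(self) -> None:
        self.ops: List = []

    def add(self, fn) -> None:
        self.ops.append(fn)

    def backward(self, loss: Var) -> None:
        loss.grad = np.ones_like(loss.data)
        for fn in reversed(self.ops):
            fn()


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(
    dcols: np.ndarray,
    x_shape: Tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    n, c, h, w = x_shape
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def conv2d(tape: Tape, x: Var, w: Var, b: Optional[Var], stride: int = 1, pad: int = 1) -> Var:
    """2D convolution, NCHW layout, square stride/padding."""
    cout, cin, kh, kw = w.data.shape
    n = x.data.shape[0]
    cols = _im2col(x.data, kh, kw, stride, pad)  # (n, cin*kh*kw, L)
    w2 = w.data.reshape(cout, -1)
    y = np.matmul(w2, cols)  # (n, cout, L)
    oh = _out_size(x.data.shape[2], kh, stride, pad)
    ow = _out_size(x.data.shape[3], kw, stride, pad)
    y = y.reshape(n, cout, oh, ow)
    if b is not None:
        y = y + b.data[None, :, None, None]
    out = Var(y)

    x_shape = x.data.shape

    def backward() -> None:
        gy = out.grad.reshape(n, cout, -1)  # (n, cout, L)
        w.accumulate(np.einsum("ncl,nkl->ck", gy, cols).reshape(w.data.shape))
        if b is not None:
            b.accumulate(gy.sum(axis=(0, 2)))
        dcols = np.matmul(w2.T, gy)  # (n, cin*kh*kw, L)
        x.accumulate(_col2im(dcols, x_shape, kh, kw, stride, pad))

    tape.add(backward)
    return out


def batchnorm2d(
    tape: Tape,
    x: Var,
    gamma: Var,
    beta: Var,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Var:
    """Per-channel batch normalization.  Running stats are updated in place."""
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = Var(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None])

    def backward() -> None:
        gy = out.grad
        gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(gy.sum(axis=(0, 2, 3)))
        dxhat = gy * gamma.data[None, :, None, None]
        if train:
            m = gy.shape[0] * gy.shape[2] * gy.shape[3]
            s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * inv_std[None, :, None, None]
        x.accumulate(dx)

    tape.add(backward)
    return out


def relu(tape: Tape, x: Var) -> Var:
    mask = x.data > 0
    out = Var(np.where(mask, x.data, 0.0))

    def backward() -> None:
        x.accumulate(out.grad * mask)

    tape.add(backward)
    return out


def add(tape: Tape, a: Var, b: Var) -> Var:
    out = Var(a.data + b.data)

    def backward() -> None:
        a.accumulate(out.grad)
        b.accumulate(out.grad)

    tape.add(backward)
    return out


def concat_channels(tape: Tape, xs: Sequence[Var]) -> Var:
    out = Var(np.concatenate([x.data for x in xs], axis=1))
    sizes = [x.data.shape[1] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def backward() -> None:
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            x.accumulate(out.grad[:, lo:hi])

    tape.add(backward)
    return out


def upsample_nearest(tape: Tape, x: Var, factor: int) -> Var:
    out = Var(x.data.repeat(factor, axis=2).repeat(factor, axis=3))
    n, c, h, w = x.data.shape

    def backward() -> None:
        g = out.grad.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x.accumulate(g)

    tape.add(backward)
    return out


def linear(tape: Tape, x: Var, w: Var, b: Var) -> Var:
    """Affine map: (N, fin) @ (fout, fin).T + (fout,)."""
    out = Var(x.data @ w.data.T + b.data)

    def backward() -> None:
        w.accumulate(out.grad.T @ x.data)
        b.accumulate(out.grad.sum(axis=0))
        x.accumulate(out.grad @ w.data)

    tape.add(backward)
    return out


def sse_loss(tape: Tape, pred: Var, target: np.ndarray, scale: float = 1.0) -> Var:
    """``scale * sum((pred - target)**2)`` as a scalar Var."""
    diff = pred.data - target
    out = Var(scale * float(np.sum(diff * diff)))

    def backward() -> None:
        pred.accumulate(out.grad * 2.0 * scale * diff)

    tape.add(backward)
    return out
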