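"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the handful of operations the segmentation networks need are provided:
3x3/1x1 convolution (implemented via im2col and BLAS matmul), ReLU, elementwise
add, 2x2 average pooling, nearest-neighbour 2x upsampling, and inverted
dropout. Forward results are plain :class:`Node` wrappers; calling
:meth:`Tape.backward` runs the recorded closures in reverse and accumulates
gradients on every node (and hence on every :class:`Param` leaf).

All computation is float32.
"""
from __future__ import annotations

from typing import Callable, List, Tuple

import numpy as np


class Node:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = None


class Param(Node):
    """A trainable leaf tensor."""


def _accum(node: Node, g: np.ndarray) -> None:
    if node.grad is None:
        node.grad = np.array(g, dtype=np.float32, copy=True)
    else:
        node.grad += g


class Tape:
    """Records operations so gradients can be propagated backwards."""

    def __init__(self) -> None:
        self._steps: List[Tuple[Node, Callable]] = []

    def _record(self, out: Node, backward: Callable) -> None:
        self._steps.append((out, backward))

    def backward(self, out: Node, grad: np.ndarray) -> None:
        _accum(out, np.asarray(grad, dtype=np.float32))
        for node, bwd in reversed(self._steps):
            if node.grad is not None:
                bwd(node.grad)


def conv2d(tape: Tape, x: Node, w: Param, b: Param) -> Node:
    """Same-padded 2-D convolution. x: (B,C,H,W); w: (O,C,k,k); b: (O,)."""
    xv, wv = x.value, w.value
    n_out, n_in, k, _ = wv.shape
    pad = k // 2
    batch, _, height, width = xv.shape
    if pad:
        xp = np.pad(xv, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = xv
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        batch, n_in * k * k, height * width)
    wm = wv.reshape(n_out, n_in * k * k)
    y = np.matmul(wm, cols).reshape(batch, n_out, height, width)
    y += b.value[None, :, None, None]
    out = Node(y)

    def bwd(g: np.ndarray) -> None:
        gm = g.reshape(batch, n_out, height * width)
        _accum(w, np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wv.shape))
        _accum(b, g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(wm.T[None], gm).reshape(batch, n_in, k, k, height, width)
        if pad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + height, j:j + width] += dcols[:, :, i, j]
            _accum(x, dxp[:, :, pad:pad + height, pad:pad + width])
        else:
            _accum(x, dcols[:, :, 0, 0])

    tape._record(out, bwd)
    return out


def relu(tape: Tape, x: Node) -> Node:
    mask = x.value > 0
    out = Node(np.where(mask, x.value, 0.0))

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * mask)

    tape._record(out, bwd)
    return out


def add(tape: Tape, a: Node, b: Node) -> Node:
    out = Node(a.value + b.value)

    def bwd(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    tape._record(out, bwd)
    return out


def avg_pool2(tape: Tape, x: Node) -> Node:
    """2x2 average pooling with stride 2; H and W must be even."""
    batch, chan, height, width = x.value.shape
    if height % 2 or width % 2:
        raise ValueError(f"avg_pool2 needs even H,W, got {height}x{width}")
    v = x.value.reshape(batch, chan, height // 2, 2, width // 2, 2)
    out = Node(v.mean(axis=(3, 5)))

    def bwd(g: np.ndarray) -> None:
        gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        _accum(x, gg)

    tape._record(out, bwd)
    return out


def upsample2(tape: Tape, x: Node) -> Node:
    """Nearest-neighbour 2x upsampling."""
    out = Node(np.repeat(np.repeat(x.value, 2, axis=2), 2, axis=3))

    def bwd(g: np.ndarray) -> None:
        batch, chan, height, width = x.value.shape
        gg = g.reshape(batch, chan, height, 2, width, 2).sum(axis=(3, 5))
        _accum(x, gg)

    tape._record(out, bwd)
    return out


def dropout(tape: Tape, x: Node, rate: float, rng: np.random.Generator,
            enabled: bool = True) -> Node:
    """Inverted dropout; identity when disabled or rate == 0."""
    if not enabled or rate == 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.value.shape) < keep).astype(np.float32) / keep
    out = Node(x.value * mask)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * mask)

    tape._record(out, bwd)
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax (outside the tape; the gradient of
    loss-through-softmax is seeded analytically by the training code)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """dL/dlogits given dL/dprobs, using the softmax Jacobian."""
    dot = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - dot)
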