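"""Minimal reverse-mode autodiff for the 3D conv nets in this package.

Only the handful of operations a U-Net needs are implemented: 3D convolution
(im2col + matmul, arbitrary per-axis stride, 'same' padding), instance
normalization, leaky ReLU, nearest-neighbour upsampling and channel
concatenation. Everything is float32 numpy; gradients flow through a tape of
``Tensor`` nodes. Deliberately small: no broadcasting rules, no graphs
beyond what the networks build.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data: np.ndarray, parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, seed: np.ndarray) -> None:
        """Backpropagate ``seed`` (dL/dself) through the tape."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.accumulate(np.asarray(seed, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# operations


def _im2col(xp: np.ndarray, kernel, stride):
    """(N, C, D, H, W) padded input -> (N*positions, C*k³) column matrix."""
    win = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    win = win[:, :, :: stride[0], :: stride[1], :: stride[2]]
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, -1)
    return np.ascontiguousarray(cols), (do, ho, wo)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, stride=(1, 1, 1)) -> Tensor:
    """'Same'-padded 3D convolution; spatial dims must be divisible by stride."""
    n, c_in, d, h, w = x.data.shape
    c_out, c_in_w, kd, kh, kw = weight.data.shape
    assert c_in == c_in_w, f"channel mismatch: {c_in} vs {c_in_w}"
    pads = ((kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + tuple((p, p) for p in pads))
    cols, (do, ho, wo) = _im2col(xp, (kd, kh, kw), stride)
    wm = weight.data.reshape(c_out, -1)
    out = cols @ wm.T + bias.data
    out = out.reshape(n, do, ho, wo, c_out).transpose(0, 4, 1, 2, 3)

    def backward(g: np.ndarray) -> None:
        g_cols = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, c_out)
        if weight.requires_grad:
            weight.accumulate((g_cols.T @ cols).reshape(weight.data.shape))
            bias.accumulate(g_cols.sum(axis=0))
        if x.requires_grad or x.parents:
            d_cols = (g_cols @ wm).reshape(n, do, ho, wo, c_in, kd, kh, kw)
            d_cols = d_cols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            dxp = np.zeros_like(xp)
            sd, sh, sw = stride
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        dxp[:, :, i: i + sd * do: sd, j: j + sh * ho: sh,
                            l: l + sw * wo: sw] += d_cols[..., i, j, l]
            x.accumulate(dxp[:, :, pads[0]: pads[0] + d, pads[1]: pads[1] + h,
                             pads[2]: pads[2] + w])

    return Tensor(out, (x, weight, bias), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-(sample, channel) normalization over spatial dims, with affine."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gam = gamma.data.reshape(1, -1, 1, 1, 1)
    out = xhat * gam + beta.data.reshape(1, -1, 1, 1, 1)

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
            beta.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x.parents:
            gx = g * gam
            m1 = gx.mean(axis=axes, keepdims=True)
            m2 = (gx * xhat).mean(axis=axes, keepdims=True)
            x.accumulate(inv * (gx - m1 - xhat * m2))

    return Tensor(out, (x, gamma, beta), backward)


def leaky_relu(x: Tensor, alpha: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * x.data)

    def backward(g: np.ndarray) -> None:
        x.accumulate(np.where(mask, g, alpha * g))

    return Tensor(out, (x,), backward)


def upsample_nearest(x: Tensor, factors) -> Tensor:
    fz, fy, fx = (int(f) for f in factors)
    out = x.data
    if fz > 1:
        out = np.repeat(out, fz, axis=2)
    if fy > 1:
        out = np.repeat(out, fy, axis=3)
    if fx > 1:
        out = np.repeat(out, fx, axis=4)

    def backward(g: np.ndarray) -> None:
        n, c, dz, dy, dx = x.data.shape
        gb = g.reshape(n, c, dz, fz, dy, fy, dx, fx).sum(axis=(3, 5, 7))
        x.accumulate(gb)

    return Tensor(out, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g: np.ndarray) -> None:
        a.accumulate(g[:, :ca])
        b.accumulate(g[:, ca:])

    return Tensor(out, (a, b), backward)
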