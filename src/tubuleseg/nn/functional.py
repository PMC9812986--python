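"""Differentiable operations on :class:`~tubuleseg.nn.tensor.Tensor`.

All image tensors use NCHW layout.  Convolutions are computed by im2col +
matrix multiply; their input gradients are scattered back with a small loop
over kernel offsets (vectorised slice-adds, no per-pixel indexing).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "add",
    "mul",
    "concat",
    "relu",
    "silu",
    "sigmoid",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2x2",
    "maxpool2d",
    "avgpool2x2",
    "global_avg_pool",
    "batchnorm2d",
    "bce_with_logits",
    "mean",
]


# --------------------------------------------------------------- elementwise
def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.shape))

    return Tensor.result(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.shape))

    return Tensor.result(out_data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate_grad(piece)

    return Tensor.result(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * mask)

    return Tensor.result(out_data, (x,), backward)


def silu(x: Tensor) -> Tensor:
    s = _sigmoid(x.data)
    out_data = x.data * s

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor.result(out_data, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid(x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * s * (1.0 - s))

    return Tensor.result(s, (x,), backward)


def mean(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.mean(), dtype=np.float32)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.full_like(x.data, g / x.data.size))

    return Tensor.result(out_data, (x,), backward)


# -------------------------------------------------------------- convolutions
def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, kh: int, kw: int, s: int) -> np.ndarray:
    """Strided sliding windows: (N, C, Ho, Wo, kh, kw) view of padded input."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::s, ::s]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with (F, C, kh, kw) weights."""
    F, C, kh, kw = w.shape
    s = stride
    xp = _pad_hw(x.data, padding)
    N, _, Hp, Wp = xp.shape
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = _windows(xp, kh, kw, s)  # (N,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    y = cols @ wmat.T
    if b is not None:
        y += b.data
    out_data = y.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            w.accumulate_grad((gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b.accumulate_grad(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x.accumulate_grad(dxp)

    return Tensor.result(out_data, (x, w) if b is None else (x, w, b), backward)


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel convolution; weights shaped (C, kh, kw)."""
    C, kh, kw = w.shape
    s = stride
    xp = _pad_hw(x.data, padding)
    N, _, Hp, Wp = xp.shape
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = _windows(xp, kh, kw, s)
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)

    def backward(g):
        if w.requires_grad:
            w.accumulate_grad(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
        if x.requires_grad:
            dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x.accumulate_grad(dxp)

    return Tensor.result(out_data, (x, w), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2 transposed convolution with stride 2 (exact upsampling, no overlap).

    Weights shaped (C_in, C_out, 2, 2); output spatial size doubles.
    """
    N, C, H, W = x.shape
    Cin, Cout, _, _ = w.shape
    blocks = np.einsum("nchw,cfij->nfhiwj", x.data, w.data, optimize=True)
    out_data = blocks.reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gb = g.reshape(N, Cout, H, 2, W, 2)
        if w.requires_grad:
            w.accumulate_grad(np.einsum("nchw,nfhiwj->cfij", x.data, gb, optimize=True))
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x.accumulate_grad(np.einsum("nfhiwj,cfij->nchw", gb, w.data, optimize=True))

    return Tensor.result(out_data, (x, w) if b is None else (x, w, b), backward)


# ------------------------------------------------------------------- pooling
def maxpool2d(x: Tensor, kernel: int = 2, stride: int = 2, padding: int = 0) -> Tensor:
    if kernel == 2 and stride == 2 and padding == 0:
        return _maxpool2x2(x)
    s = stride
    xp = _pad_hw(x.data, padding)
    if padding:
        xp[:, :, :padding, :] = -np.inf
        xp[:, :, -padding:, :] = -np.inf
        xp[:, :, :, :padding] = -np.inf
        xp[:, :, :, -padding:] = -np.inf
    N, C, Hp, Wp = xp.shape
    Ho = (Hp - kernel) // s + 1
    Wo = (Wp - kernel) // s + 1
    win = _windows(xp, kernel, kernel, s).reshape(N, C, Ho, Wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((N, C, Hp * Wp), dtype=np.float32)
        ki, kj = np.divmod(idx, kernel)  # (N,C,Ho,Wo)
        rows = (np.arange(Ho)[None, None, :, None] * s) + ki
        cols = (np.arange(Wo)[None, None, None, :] * s) + kj
        flat = (rows * Wp + cols).reshape(N, C, -1)
        np.add.at(dxp, (np.arange(N)[:, None, None], np.arange(C)[None, :, None], flat), g.reshape(N, C, -1))
        dxp = dxp.reshape(N, C, Hp, Wp)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.accumulate_grad(dxp)

    return Tensor.result(out_data, (x,), backward)


def _maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]

    def backward(g):
        if not x.requires_grad:
            return
        gexp = g[:, :, :, None, :, None] * mask
        # normalise where several cells tie for the max
        counts = mask.sum(axis=(3, 5))[:, :, :, None, :, None]
        gexp = gexp / counts
        x.accumulate_grad(gexp.reshape(N, C, H, W))

    return Tensor.result(out_data, (x,), backward)


def avgpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = r.mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gexp = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x.accumulate_grad(gexp)

    return Tensor.result(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(g / (H * W), x.shape).astype(np.float32))

    return Tensor.result(out_data, (x,), backward)


# ----------------------------------------------------------------- batchnorm
def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays mutated in place when
    training (standard exponential moving average of batch statistics).
    """
    N, C, H, W = x.shape
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        n = N * H * W
        unbiased = v * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        m = running_mean
        v = running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                n = N * H * W
                sum_gi = gi.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gi - sum_gi / n - xhat * sum_gx / n) * inv[None, :, None, None]
            else:
                dx = gi * inv[None, :, None, None]
            x.accumulate_grad(dx.astype(np.float32))

    return Tensor.result(out_data, (x, gamma, beta), backward)


# --------------------------------------------------------------------- loss
def bce_with_logits(logits: Tensor, targets: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Mean per-pixel binary cross entropy computed from logits (stable form)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float32)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        per = per * weight
        denom = float(weight.sum())
    else:
        denom = per.size
    out_data = np.asarray(per.sum() / denom, dtype=np.float32)

    def backward(g):
        if logits.requires_grad:
            dz = (_sigmoid(z) - y)
            if weight is not None:
                dz = dz * weight
            logits.accumulate_grad(g * dz / denom)

    return Tensor.result(out_data, (logits,), backward)
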