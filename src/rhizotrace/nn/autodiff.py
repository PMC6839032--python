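"""A compact reverse-mode autodiff engine over numpy arrays.

Implements exactly the operations the segmentation/localization network
needs — strided convolution, 2x2/stride-2 transposed convolution, batch
normalization, ReLU, 2x2 max pooling, 2x bilinear upsampling, elementwise
add, and two fused loss heads (weighted binary cross-entropy on logits and
weighted squared error) — each with a hand-written adjoint.  Convolutions
run as im2col + BLAS matmul in float32.

The design is deliberately small: a :class:`Tensor` records its parents
and a backward closure; :func:`Tensor.backward` topologically sorts the
graph and accumulates gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "conv_transpose2d_2x",
    "batch_norm",
    "relu",
    "maxpool2x2",
    "upsample_bilinear2x",
    "add",
    "weighted_bce_with_logits",
    "weighted_mse",
    "add_scalars",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = live
    out.requires_grad = bool(live)
    out._backward = backward if live else None
    return out


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = v.shape[:4]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * ho * wo, c * kh * kw
    )
    return cols, (b, ho, wo)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dxp = np.zeros((b, c, hp, wp), dtype=np.float32)
    d = dcols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                d[:, :, :, :, i, j]
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Fast path: pointwise convolution as a single channel-mixing matmul."""
    o, c = w.shape[:2]
    bb, _, h, ww = x.shape
    wmat = w.data.reshape(o, c)
    xm = x.data.reshape(bb, c, h * ww)
    out = np.matmul(wmat, xm)  # (bb, o, h*ww)
    if b is not None:
        out += b.data[None, :, None]
    out = out.reshape(bb, o, h, ww)

    def backward(gy):
        gym = gy.reshape(bb, o, h * ww)
        if w.requires_grad:
            gw = np.einsum("boi,bci->oc", gym, xm, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dx = np.matmul(wmat.T, gym).reshape(x.data.shape)
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); weight layout (O, C, kh, kw)."""
    o, c, kh, kw = w.shape
    if kh == kw == 1 and stride == 1 and pad == 0:
        return _conv1x1(x, w, b)
    cols, (bb, ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(o, c * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(bb, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(gy):
        gy_cols = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, o)
        if w.requires_grad:
            w._accumulate((gy_cols.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gy_cols.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = gy_cols @ wmat
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv_transpose2d_2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2; weight layout (C, O, 2, 2).

    Doubles the spatial size: each input pixel paints one disjoint 2x2
    output block, so forward and adjoint are simple matmuls.
    """
    c, o = w.shape[:2]
    bb, _, h, ww = x.shape
    xmat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, c)
    wmat = w.data.reshape(c, o * 4)
    out = (xmat @ wmat).reshape(bb, h, ww, o, 2, 2)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 4, 2, 5)).reshape(
        bb, o, 2 * h, 2 * ww
    )
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(gy):
        g = gy.reshape(bb, o, h, 2, ww, 2).transpose(0, 2, 4, 1, 3, 5)
        gmat = np.ascontiguousarray(g).reshape(-1, o * 4)
        if w.requires_grad:
            w._accumulate((xmat.T @ gmat).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dx = (gmat @ wmat.T).reshape(bb, h, ww, c).transpose(0, 3, 1, 2)
            x._accumulate(np.ascontiguousarray(dx))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# ---------------------------------------------------------------------------
# normalization / activations / pooling / resizing


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (B, H, W) per channel, with affine terms.

    In training mode, batch statistics are used and the running statistics
    are updated in place; in eval mode the running statistics are used.
    """
    if training:
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        xs = x.data.sum(axis=(0, 2, 3), dtype=np.float64)
        xss = np.einsum("bchw,bchw->c", x.data, x.data, optimize=True)
        mean = (xs / n).astype(np.float32)
        var = np.maximum(xss / n - mean.astype(np.float64) ** 2, 0.0).astype(
            np.float32
        )
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gy):
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            g = gy * gamma.data[None, :, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gs = g.sum(axis=(0, 2, 3))
                gxs = (g * xhat).sum(axis=(0, 2, 3))
                dx = (
                    g
                    - gs[None, :, None, None] / n
                    - xhat * gxs[None, :, None, None] / n
                ) * inv[None, :, None, None]
            else:
                dx = g * inv[None, :, None, None]
            x._accumulate(dx.astype(np.float32))

    return _node(out.astype(np.float32), (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(gy):
        x._accumulate(gy * mask)

    return _node(out, (x,), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    v = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(b, c, h // 2, w // 2, 4)
    arg = v.argmax(axis=-1)
    out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]

    def backward(gy):
        dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dv, arg[..., None], gy[..., None], axis=-1)
        dx = dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.ascontiguousarray(dx).reshape(b, c, h, w))

    return _node(out, (x,), backward)


def _up1d(a: np.ndarray, axis: int) -> np.ndarray:
    """2x bilinear upsampling along one axis (align_corners=False)."""
    a = np.moveaxis(a, axis, -1)
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    out[..., 0::2] = 0.75 * a + 0.25 * left
    out[..., 1::2] = 0.75 * a + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up1d_adj(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    da = 0.75 * (ge + go)
    # adjoint of the "left" gather: shift contributions right, clamp at edge
    da[..., :-1] += 0.25 * ge[..., 1:]
    da[..., 0] += 0.25 * ge[..., 0]
    # adjoint of the "right" gather
    da[..., 1:] += 0.25 * go[..., :-1]
    da[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(da, -1, axis)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    out = _up1d(_up1d(x.data, 2), 3)

    def backward(gy):
        x._accumulate(_up1d_adj(_up1d_adj(gy, 3), 2).astype(np.float32))

    return _node(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(gy):
        if a.requires_grad or a._parents:
            a._accumulate(gy)
        if b.requires_grad or b._parents:
            b._accumulate(gy)

    return _node(out, (a, b), backward)


# ---------------------------------------------------------------------------
# fused loss heads


def weighted_bce_with_logits(
    logits: Tensor, target: np.ndarray, channel_weights: np.ndarray
) -> Tensor:
    """Per-channel-weighted binary cross-entropy, summed over pixels.

    Computes sum_c w_c * sum_{b,x,y} BCE(sigmoid(z), g) / B, i.e. the
    spatial sums of the balanced cross-entropy averaged over the batch.
    Numerically stable log-sum-exp form; gradient is w_c*(sigmoid(z)-g)/B.
    """
    z = logits.data
    g = np.asarray(target, dtype=np.float32)
    w = np.asarray(channel_weights, dtype=np.float32)[None, :, None, None]
    batch = z.shape[0]
    # max(z,0) - z*g + log(1+exp(-|z|))
    per = np.maximum(z, 0) - z * g + np.log1p(np.exp(-np.abs(z)))
    val = float((w * per).sum() / batch)

    def backward(gy):
        sig = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(gy * w * (sig - g) / batch)

    return _node(np.float32(val), (logits,), backward)


def weighted_mse(
    pred: Tensor, target: np.ndarray, channel_weights: np.ndarray
) -> Tensor:
    """Per-channel-weighted squared error, summed over pixels, batch-averaged."""
    p = np.asarray(target, dtype=np.float32)
    w = np.asarray(channel_weights, dtype=np.float32)[None, :, None, None]
    diff = pred.data - p
    batch = pred.data.shape[0]
    val = float((w * diff * diff).sum() / batch)

    def backward(gy):
        pred._accumulate(gy * 2.0 * w * diff / batch)

    return _node(np.float32(val), (pred,), backward)


def add_scalars(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(gy):
        a._accumulate(gy)
        b._accumulate(gy)

    return _node(out, (a, b), backward)
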