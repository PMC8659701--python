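"""Structured ops on Tensors: convolution, resampling, pooling, losses.

Convolution uses an im2col forward (``sliding_window_view`` + einsum) and a
slice-scatter backward, which is fast enough at the spatial sizes this
package trains at.  The bilinear resamplers carry gradients with respect to
the feature map only — sample coordinates are treated as constants, as in
standard RoI-Align.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (O,C,kh,kw) -> (N,O,Ho,Wo)."""
    kh, kw = w.shape[2], w.shape[3]
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh_eff, kw_eff), axis=(2, 3))
    cols = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)
    n, c, hp, wp = xp.shape
    ho, wo = out_data.shape[2], out_data.shape[3]

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nohw->ocij", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
            for i in range(kh):
                ii = i * dilation
                for j in range(kw):
                    jj = j * dilation
                    dxp[:, :, ii:ii + ho * stride:stride,
                        jj:jj + wo * stride:stride] += dcols[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)

    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map: x (N, D) @ w (D, M) + b (M,)."""
    out = x @ w
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# resampling / pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (input sides must divide by k)."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    view = x.data[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        dx = dx.reshape(n, c, ho * k, wo * k)
        if dx.shape != x.data.shape:
            full = np.zeros_like(x.data)
            full[:, :, :ho * k, :wo * k] = dx
            dx = full
        x._accum(dx)

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): per-channel spatial mean."""
    return x.mean(axis=(2, 3))


def _bilinear_weights(length_out: int, length_in: int, factor: float):
    # half-pixel-center mapping, clipped at the borders
    coords = (np.arange(length_out) + 0.5) / factor - 0.5
    coords = np.clip(coords, 0, length_in - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, length_in - 1)
    frac = coords - lo
    return lo, hi, frac


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling of (N, C, H, W) by an integer factor."""
    n, c, h, w = x.shape
    ho, wo = h * factor, w * factor
    ylo, yhi, fy = _bilinear_weights(ho, h, factor)
    xlo, xhi, fx = _bilinear_weights(wo, w, factor)
    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * ((1 - fy)[:, None] * (1 - fx)[None, :]) \
        + d[:, :, ylo][:, :, :, xhi] * ((1 - fy)[:, None] * fx[None, :])
    bot = d[:, :, yhi][:, :, :, xlo] * (fy[:, None] * (1 - fx)[None, :]) \
        + d[:, :, yhi][:, :, :, xhi] * (fy[:, None] * fx[None, :])
    out = Tensor(top + bot, parents=(x,))

    def bwd(g):
        dx = np.zeros_like(d)
        for wy, yidx in (((1 - fy), ylo), (fy, yhi)):
            for wx, xidx in (((1 - fx), xlo), (fx, xhi)):
                contrib = g * (wy[:, None] * wx[None, :])
                np.add.at(dx, (slice(None), slice(None), yidx[:, None],
                               xidx[None, :]), contrib)
        x._accum(dx)

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor."""
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3),
                 parents=(x,))

    def bwd(g):
        gr = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(gr)

    out._backward = bwd
    return out


def bilinear_sample(fmap: Tensor, xs: np.ndarray, ys: np.ndarray) -> Tensor:
    """Sample a (C, H, W) map at fractional (xs, ys); out-of-bounds -> 0.

    Returns a (C, P) Tensor.  Gradients flow to the feature map only.
    """
    c, h, w = fmap.shape
    xs = np.asarray(xs, dtype=float).ravel()
    ys = np.asarray(ys, dtype=float).ravel()
    valid = (xs > -1) & (xs < w) & (ys > -1) & (ys < h)
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    d = fmap.data
    acc = np.zeros((c, xs.size), dtype=d.dtype)
    corners = []
    for yi, wy in ((y0, 1 - fy), (y0 + 1, fy)):
        for xi, wx in ((x0, 1 - fx), (x0 + 1, fx)):
            ok = valid & (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            wgt = np.where(ok, wy * wx, 0.0)
            xi_c = np.clip(xi, 0, w - 1)
            yi_c = np.clip(yi, 0, h - 1)
            acc += d[:, yi_c, xi_c] * wgt
            corners.append((yi_c, xi_c, wgt))
    out = Tensor(acc, parents=(fmap,))

    def bwd(g):
        df = np.zeros_like(d)
        for yi_c, xi_c, wgt in corners:
            np.add.at(df, (slice(None), yi_c, xi_c), g * wgt)
        fmap._accum(df)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# losses (fused forward/backward for numerical stability)
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross entropy of (N, K) logits against integer labels (N,)."""
    labels = np.asarray(labels, dtype=int)
    n = logits.shape[0]
    p = softmax(logits.data, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    out = Tensor(loss, parents=(logits,))

    def bwd(g):
        dp = p.copy()
        dp[np.arange(n), labels] -= 1.0
        logits._accum(g * dp / n)

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross entropy on raw logits (elementwise targets in [0,1])."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*t, numerically stable
    loss_el = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        loss_el = loss_el * weights
        denom = float(np.sum(weights)) + 1e-12
    else:
        denom = float(loss_el.size)
    out = Tensor(loss_el.sum() / denom, parents=(logits,))
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def bwd(g):
        d = (s - t)
        if weights is not None:
            d = d * weights
        logits._accum(g * d / denom)

    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0,
              reduction: str = "mean") -> Tensor:
    """Huber / smooth-L1 loss on raw differences."""
    t = np.asarray(target, dtype=pred.data.dtype)
    d = pred.data - t
    ad = np.abs(d)
    loss_el = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    if reduction == "mean":
        denom = float(loss_el.size)
    elif reduction == "sum":
        denom = 1.0
    else:
        raise ValueError(reduction)
    out = Tensor(loss_el.sum() / denom, parents=(pred,))

    def bwd(g):
        dd = np.where(ad < beta, d / beta, np.sign(d))
        pred._accum(g * dd / denom)

    out._backward = bwd
    return out
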