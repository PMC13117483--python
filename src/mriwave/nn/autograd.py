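"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the four-band attention U-Net needs:
2D convolution (any kernel/stride, zero padding), 2x2 max pooling, factor-2
bilinear upsampling, batch normalization, LeakyReLU/ReLU/sigmoid, channel
concatenation, broadcast multiplication, elementwise addition, and the
band-weighted L1 loss.  Gradients propagate through a dynamically built tape;
float32 throughout.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


def _node(data, parents, backward):
    rg = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=rg, parents=[p for p in parents if p.requires_grad],
                  backward=backward if rg else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def _unbroadcast(g, shape):
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x._accum(np.where(mask, g, np.float32(slope) * g))

    return _node(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, slope=0.0)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data, dtype=np.float32))

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return _node(out_data, (a, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of (B,C,H,W) with (O,C,k,k) weights."""
    B, C, H, W = x.data.shape
    O, Cw, k, _ = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2:]
    Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
    out = np.zeros((B, O, Ho, Wo), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            xs = xp[:, :, ki: ki + s * Ho: s, kj: kj + s * Wo: s]
            out += np.einsum("oc,bchw->bohw", w.data[:, :, ki, kj], xs, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad or x.requires_grad:
            dxp = np.zeros_like(xp) if x.requires_grad else None
            for ki in range(k):
                for kj in range(k):
                    xs = xp[:, :, ki: ki + s * Ho: s, kj: kj + s * Wo: s]
                    if w.requires_grad:
                        dw = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, ki, kj] += dw
                    if dxp is not None:
                        dxp[:, :, ki: ki + s * Ho: s, kj: kj + s * Wo: s] += np.einsum(
                            "oc,bohw->bchw", w.data[:, :, ki, kj], g, optimize=True)
            if dxp is not None:
                x._accum(dxp[:, :, p: Hp - p, p: Wp - p] if p else dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(H, W)}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(B, C, H, W))

    return _node(out, (x,), backward)


_UPSAMPLE_CACHE: dict = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) factor-2 bilinear interpolation matrix (half-pixel centers)."""
    if n not in _UPSAMPLE_CACHE:
        U = np.zeros((2 * n, n), dtype=np.float32)
        for i in range(n):
            U[2 * i, max(i - 1, 0)] += 0.25
            U[2 * i, i] += 0.75
            U[2 * i + 1, i] += 0.75
            U[2 * i + 1, min(i + 1, n - 1)] += 0.25
        _UPSAMPLE_CACHE[n] = U
    return _UPSAMPLE_CACHE[n]


def upsample2_bilinear(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    Uh, Uw = _upsample_matrix(H), _upsample_matrix(W)
    out = np.einsum("Hh,bchw,Ww->bcHW", Uh, x.data, Uw, optimize=True)

    def backward(g):
        x._accum(np.einsum("Hh,bcHW,Ww->bchw", Uh, g, Uw, optimize=True))

    return _node(out.astype(np.float32), (x,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalization; updates running stats in place when training."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(np.float32)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                N = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                mean_gxh = gxh.mean(axis=(0, 2, 3))
                mean_gxh_xhat = (gxh * xhat).mean(axis=(0, 2, 3))
                dx = (gxh - mean_gxh[None, :, None, None]
                      - xhat * mean_gxh_xhat[None, :, None, None]) / std[None, :, None, None]
            else:
                dx = gxh / std[None, :, None, None]
            x._accum(dx.astype(np.float32))

    return _node(out.astype(np.float32), (x, gamma, beta), backward)


def band_weighted_l1(pred: Tensor, target: np.ndarray, weights) -> Tensor:
    """sum_b w_b * mean(|pred[:, b] - target[:, b]|) over batch and space."""
    t = np.asarray(target, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {t.shape}")
    w = np.asarray(weights, dtype=np.float32)
    if w.shape != (pred.data.shape[1],):
        raise ValueError("one weight per band channel required")
    diff = pred.data - t
    per_band = np.abs(diff).mean(axis=(0, 2, 3))
    out = (w * per_band).sum()

    def backward(g):
        B, C, H, W = diff.shape
        scale = (w / (B * H * W)).astype(np.float32)
        pred._accum(g * np.sign(diff) * scale[None, :, None, None])

    return _node(np.float32(out), (pred,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
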