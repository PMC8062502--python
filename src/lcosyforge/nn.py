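"""Minimal CPU convolutional-network engine used by the D-UNet models.

A small reverse-mode autodiff core over numpy arrays with exactly the
operations the densely connected U-Net needs: 3x3/1x1 same-padded
convolutions, ReLU, 2x2 max pooling, 2x nearest upsampling, channel
concatenation and mean-squared-error loss, plus an Adam optimizer.

Activations are held in channels-last (N, H, W, C) layout so that every
convolution reduces to BLAS matrix products over contiguous slices: a 3x3
convolution is accumulated from nine shifted views of the padded input,
each of which is a contiguous-chunk copy followed by one sgemm.  Everything
runs in float32 and all randomness flows through explicit numpy Generators,
so training is bit-reproducible on a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Param", "Conv2d", "relu", "relu_channels", "abs_channels", "maxpool2",
           "upsample2", "concat", "scale", "mse_loss", "Adam"]


class Tensor:
    """Node in the computation graph; data layout is (N, H, W, C)."""

    __slots__ = ("data", "grad", "parents", "bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = data
        self.grad = None
        self.parents = parents
        self.bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def _add_grad(self, g):
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else g
        else:
            self.grad += g

    def backward(self):
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t.bwd is not None and t.grad is not None:
                t.bwd(t.grad)


class Param:
    """Trainable array with accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


# ---------------------------------------------------------------------------
# layers / ops
# ---------------------------------------------------------------------------

class Conv2d:
    """Same-padded convolution, kernel 3x3 or 1x1, stride 1.

    Weights are stored as (kh, kw, in_ch, out_ch) with He-style fan-in
    initialization.
    """

    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        w = rng.standard_normal((kernel, kernel, in_ch, out_ch))
        self.weight = Param(w * np.sqrt(2.0 / fan_in))
        self.bias = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        n, h, w, c = x.data.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        W = self.weight.data
        if k == 1:
            flat = x.data.reshape(-1, c)
            y = flat @ W[0, 0] + self.bias.data
            out = Tensor(y.reshape(n, h, w, self.out_ch), (x,))

            def bwd1(gy):
                gy2 = gy.reshape(-1, self.out_ch)
                self.weight.grad[0, 0] += flat.T @ gy2
                self.bias.grad += gy2.sum(axis=0)
                x._add_grad((gy2 @ W[0, 0].T).reshape(x.data.shape))

            out.bwd = bwd1
            return out

        # zero-padded input; the nine kernel taps are each one full-grid
        # sgemm followed by a shifted accumulation (no gather copies)
        xp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        xp[:, 1:-1, 1:-1, :] = x.data
        flat = xp.reshape(-1, c)
        y = np.zeros((n, h, w, self.out_ch), dtype=np.float32)
        y += self.bias.data
        for ky in range(3):
            for kx in range(3):
                yf = flat @ W[ky, kx]
                y += yf.reshape(n, h + 2, w + 2, self.out_ch)[
                    :, ky:ky + h, kx:kx + w, :]
        out = Tensor(y, (x,))

        def bwd(gy):
            gy2 = gy.reshape(-1, self.out_ch)
            self.bias.grad += gy2.sum(axis=0)
            gxp = np.zeros_like(xp)
            canvas = np.zeros((n, h + 2, w + 2, self.out_ch),
                              dtype=np.float32)
            for ky in range(3):
                for kx in range(3):
                    canvas[...] = 0
                    canvas[:, ky:ky + h, kx:kx + w, :] = gy
                    self.weight.grad[ky, kx] += flat.T @ canvas.reshape(
                        -1, self.out_ch)
                    gxp[:, ky:ky + h, kx:kx + w, :] += \
                        (gy2 @ W[ky, kx].T).reshape(n, h, w, c)
            x._add_grad(np.ascontiguousarray(gxp[:, 1:1 + h, 1:1 + w, :]))

        out.bwd = bwd
        return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), (x,))
    out.bwd = lambda gy: x._add_grad(gy * mask)
    return out


def relu_channels(x: Tensor, channels) -> Tensor:
    """ReLU applied only to the given channel indices (last axis)."""
    mask = np.ones_like(x.data, dtype=bool)
    mask[..., channels] = x.data[..., channels] > 0
    out = Tensor(np.where(mask, x.data, 0), (x,))
    out.bwd = lambda gy: x._add_grad(gy * mask)
    return out


def abs_channels(x: Tensor, channels) -> Tensor:
    """Magnitude (|x|) on the given channel indices (last axis); unlike a
    ReLU it is non-negative without a zero-gradient region, so output
    channels cannot die during training."""
    sign = np.ones_like(x.data)
    sign[..., channels] = np.sign(x.data[..., channels])
    out = Tensor(x.data * sign, (x,))
    out.bwd = lambda gy: x._add_grad(gy * sign)
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    v = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = v.max(axis=(2, 4))
    argmask = v == out_data[:, :, None, :, None, :]
    out = Tensor(out_data, (x,))

    def bwd(gy):
        g = argmask * gy[:, :, None, :, None, :]
        x._add_grad(g.reshape(n, h, w, c))

    out.bwd = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), (x,))

    def bwd(gy):
        g = gy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
        x._add_grad(g)

    out.bwd = bwd
    return out


def concat(tensors) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[-1] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1),
                 tuple(tensors))

    def bwd(gy):
        i = 0
        for t, s in zip(tensors, sizes):
            t._add_grad(np.ascontiguousarray(gy[..., i:i + s]))
            i += s

    out.bwd = bwd
    return out


def scale(x: Tensor, k: float) -> Tensor:
    out = Tensor(x.data * np.float32(k), (x,))
    out.bwd = lambda gy: x._add_grad(gy * np.float32(k))
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out = Tensor(np.asarray(np.mean(diff ** 2), dtype=np.float32), (pred,))
    out.bwd = lambda gy: pred._add_grad((2.0 / diff.size) * diff * gy)
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            p.data -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
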