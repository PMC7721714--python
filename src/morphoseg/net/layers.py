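"""Pseudo-3D network layers with explicit forward/backward passes.

All tensors are (N, C, D, H, W). In-plane convolutions use 3x3x1 kernels
(depth extent 1), the depth-fusing convolution uses 1x1x3, pooling and
upsampling act in-plane only so the slice count is preserved end to end.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .autodiff import Node, Param, Tape


class Layer:
    def params(self) -> list[Param]:
        return [v for v in vars(self).values() if isinstance(v, Param)]


class Conv(Layer):
    """Small-kernel 3D convolution, 'same' padding, per-axis dilation."""

    def __init__(self, c_in: int, c_out: int, ksize=(1, 3, 3),
                 dilation=(1, 1, 1), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * int(np.prod(ksize))
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, c_in, *ksize)))
        self.b = Param(np.zeros(c_out))
        self.ksize = tuple(ksize)
        self.dilation = tuple(dilation)

    def __call__(self, tape: Tape, x: Node) -> Node:
        ks, dil = self.ksize, self.dilation
        pad = tuple(d * (k - 1) // 2 for k, d in zip(ks, dil))
        xv = x.value
        N, C, D, H, W = xv.shape
        xp = np.pad(xv, ((0, 0), (0, 0), (pad[0], pad[0]),
                         (pad[1], pad[1]), (pad[2], pad[2])))
        taps = list(product(range(ks[0]), range(ks[1]), range(ks[2])))
        outT = np.zeros((N, D, H, W, self.W.value.shape[0]))
        for (i, j, k) in taps:
            o = (i * dil[0], j * dil[1], k * dil[2])
            xs = xp[:, :, o[0]:o[0] + D, o[1]:o[1] + H, o[2]:o[2] + W]
            outT += np.tensordot(xs, self.W.value[:, :, i, j, k], axes=([1], [1]))
        out = outT.transpose(0, 4, 1, 2, 3) + self.b.value[None, :, None, None, None]

        def bw(g):
            gT = g.transpose(0, 2, 3, 4, 1)
            self.b.grad += gT.sum(axis=(0, 1, 2, 3))
            gxp = np.zeros_like(xp)
            for (i, j, k) in taps:
                o = (i * dil[0], j * dil[1], k * dil[2])
                sl = (slice(None), slice(None), slice(o[0], o[0] + D),
                      slice(o[1], o[1] + H), slice(o[2], o[2] + W))
                xs = xp[sl]
                self.W.grad[:, :, i, j, k] += np.tensordot(
                    gT, xs, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                gxp[sl] += np.tensordot(
                    gT, self.W.value[:, :, i, j, k], axes=([4], [0])
                ).transpose(0, 4, 1, 2, 3)
            gx = gxp[:, :, pad[0]:pad[0] + D, pad[1]:pad[1] + H, pad[2]:pad[2] + W]
            return (gx,)

        return tape.node(out, (x,), bw)


class GroupNorm(Layer):
    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def __call__(self, tape: Tape, x: Node) -> Node:
        xv = x.value
        N, C, D, H, W = xv.shape
        G = self.groups
        xg = xv.reshape(N, G, C // G, D, H, W)
        mu = xg.mean(axis=(2, 3, 4, 5), keepdims=True)
        var = xg.var(axis=(2, 3, 4, 5), keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (xg - mu) / std
        xhat_f = xhat.reshape(N, C, D, H, W)
        out = self.gamma.value[None, :, None, None, None] * xhat_f \
            + self.beta.value[None, :, None, None, None]

        def bw(g):
            self.gamma.grad += (g * xhat_f).sum(axis=(0, 2, 3, 4))
            self.beta.grad += g.sum(axis=(0, 2, 3, 4))
            dxhat = (g * self.gamma.value[None, :, None, None, None]) \
                .reshape(N, G, C // G, D, H, W)
            m1 = dxhat.mean(axis=(2, 3, 4, 5), keepdims=True)
            m2 = (dxhat * xhat).mean(axis=(2, 3, 4, 5), keepdims=True)
            dx = (dxhat - m1 - xhat * m2) / std
            return (dx.reshape(N, C, D, H, W),)

        return tape.node(out, (x,), bw)


class PReLU(Layer):
    def __init__(self, init: float = 0.25):
        self.a = Param(np.array(init))

    def __call__(self, tape: Tape, x: Node) -> Node:
        xv = x.value
        pos = xv > 0
        out = np.where(pos, xv, self.a.value * xv)

        def bw(g):
            self.a.grad += (g * np.minimum(xv, 0.0)).sum()
            return (g * np.where(pos, 1.0, self.a.value),)

        return tape.node(out, (x,), bw)


def maxpool_hw(tape: Tape, x: Node) -> Node:
    """2x2 in-plane max pooling (depth untouched)."""
    xv = x.value
    N, C, D, H, W = xv.shape
    xr = xv.reshape(N, C, D, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 3, 5, 4, 6) \
        .reshape(N, C, D, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gr = np.zeros((N, C, D, H // 2, W // 2, 4))
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(N, C, D, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6) \
            .reshape(N, C, D, H, W)
        return (gx,)

    return tape.node(out, (x,), bw)


def _up1d(v: np.ndarray, axis: int) -> np.ndarray:
    v = np.moveaxis(v, axis, 0)
    n = v.shape[0]
    out = np.empty((2 * n,) + v.shape[1:], dtype=v.dtype)
    out[0::2] = v
    out[1:-1:2] = 0.5 * (v[:-1] + v[1:])
    out[-1] = v[-1]
    return np.moveaxis(out, 0, axis)


def _up1d_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    n = g.shape[0] // 2
    ge, go = g[0::2], g[1::2]
    gx = ge.copy()
    gx[:-1] += 0.5 * go[:-1]
    gx[1:] += 0.5 * go[:-1]
    gx[-1] += go[-1]
    return np.moveaxis(gx, 0, axis)


def upsample_hw(tape: Tape, x: Node) -> Node:
    """2x linear in-plane upsampling (y[2i] = x[i], y[2i+1] = midpoint)."""
    out = _up1d(_up1d(x.value, 3), 4)

    def bw(g):
        return (_up1d_adjoint(_up1d_adjoint(g, 4), 3),)

    return tape.node(out, (x,), bw)


def concat_channels(tape: Tape, nodes: list[Node]) -> Node:
    sizes = [n.value.shape[1] for n in nodes]
    out = np.concatenate([n.value for n in nodes], axis=1)

    def bw(g):
        grads, at = [], 0
        for s in sizes:
            grads.append(g[:, at:at + s])
            at += s
        return tuple(grads)

    return tape.node(out, tuple(nodes), bw)


def add(tape: Tape, a: Node, b: Node) -> Node:
    return tape.node(a.value + b.value, (a, b), lambda g: (g, g))


def crop_depth(tape: Tape, x: Node, exclude: int) -> Node:
    if exclude == 0:
        return x
    D = x.value.shape[2]
    out = x.value[:, :, exclude:D - exclude]

    def bw(g):
        gx = np.zeros_like(x.value)
        gx[:, :, exclude:D - exclude] = g
        return (gx,)

    return tape.node(out, (x,), bw)


def constant(tape: Tape, value: np.ndarray) -> Node:
    return tape.node(np.asarray(value, dtype=np.float64))


def avgpool_hw(v: np.ndarray) -> np.ndarray:
    """Plain 2x2 in-plane average pooling (used for the raw-input pyramid,
    which carries no gradient)."""
    N, C, D, H, W = v.shape
    return v.reshape(N, C, D, H // 2, 2, W // 2, 2).mean(axis=(4, 6))
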