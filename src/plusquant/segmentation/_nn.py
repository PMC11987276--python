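"""Minimal CPU neural-network core for the vessel segmenter.

A small set of layers (3x3/1x1 convolution, ReLU, 2x2 max-pool, nearest
upsampling, channel concatenation, sigmoid) with hand-written backward
passes, assembled into a configurable-depth U-Net and trained with Adam.
Everything runs in float32 on plain numpy; convolutions use an im2col
lowering to matrix multiplication.  Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """Same-padded stride-1 convolution with bias.

    Implemented as k*k channel-mixing matmuls over shifted slices of the
    zero-padded input — cheaper in memory traffic than an im2col
    lowering for small kernels.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @staticmethod
    def _shift_conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Correlate (N,Cin,H,W) with (Cout,Cin,k,k), 'same' zero padding."""
        n, c, h, wd = x.shape
        k = w.shape[-1]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, w.shape[0], h, wd), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + h, j : j + wd]
                out += np.tensordot(patch, w[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self._shift_conv(x, self.W) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, wd = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + h, j : j + wd]
                # sum over n,h,w: (Cout, Cin)
                self.gW[:, :, i, j] += np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
        self.gb += dout.sum(axis=(0, 2, 3))
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return self._shift_conv(dout, w_flip)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling; input height/width must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


class Sigmoid:
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)

    def params(self):
        return []


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv2d(c_in, c_out, 3, rng), ReLU(), Conv2d(c_out, c_out, 3, rng), ReLU()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def params(self):
        return [p for lay in self.layers for p in lay.params()]


class UNet:
    """U-Net with `depth` resolution levels (depth-1 poolings).

    depth=3, base=16 gives encoder channels 16/32 and a 64-channel
    bottleneck — small enough to train on one CPU core.
    """

    def __init__(self, depth: int = 3, base: int = 16, in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base = base
        self.in_channels = in_channels
        self.enc = []
        c_in = in_channels
        for d in range(depth - 1):
            c_out = base * 2**d
            self.enc.append(_ConvBlock(c_in, c_out, rng))
            c_in = c_out
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.bottleneck = _ConvBlock(c_in, base * 2 ** (depth - 1), rng)
        self.ups = [Upsample2() for _ in range(depth - 1)]
        self.dec = []
        c_in = base * 2 ** (depth - 1)
        for d in reversed(range(depth - 1)):
            skip = base * 2**d
            self.dec.append(_ConvBlock(c_in + skip, skip, rng))
            c_in = skip
        self.head = Conv2d(c_in, 1, 1, rng)
        self.out_act = Sigmoid()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1))
        x = self.head.forward(x)
        return self.out_act.forward(x)

    def backward(self, dout: np.ndarray) -> None:
        d = self.out_act.backward(dout)
        d = self.head.backward(d)
        dskips = []
        for blk, up, n_skip in zip(reversed(self.dec), reversed(self.ups), reversed(self._skip_ch)):
            d = blk.backward(d)
            dskips.append(d[:, :n_skip])
            d = up.backward(d[:, n_skip:])
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> list:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for (w, _), new in zip(own, weights):
            w[...] = np.asarray(new, dtype=np.float32).reshape(w.shape)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
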