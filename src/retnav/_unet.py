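"""Compact 2D U-Net in pure NumPy with manual backpropagation.

A small multi-scale encoder-decoder for B-scan lesion segmentation: double
3x3 conv + ReLU blocks, 2x2 max pooling, nearest-neighbour upsampling with
skip concatenation, and a 1x1 output head producing one logit per pixel.
Training uses Adam on sigmoid cross-entropy optionally mixed with a soft
Dice term.  Convolutions are evaluated through sliding-window views and
einsum (BLAS-backed); everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same conv. x (N,C,H,W), w (O,C,3,3), b (O,)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    xw = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    out = np.einsum("nchwij,ocij->nohw", xw, w, optimize=True) + b[None, :, None, None]
    return out, xw


def _conv_backward(dout: np.ndarray, xw: np.ndarray, w: np.ndarray, x_shape):
    dw = np.einsum("nchwij,nohw->ocij", xw, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    n, c, h, wd = x_shape
    dxp = np.zeros((n, c, h + 2, wd + 2), dtype=dout.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + wd] += np.einsum(
                "nohw,oc->nchw", dout, w[:, :, i, j], optimize=True
            )
    return dxp[:, :, 1:-1, 1:-1], dw, db


class _Conv:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        self.kernel = kernel
        scale = np.sqrt(2.0 / (cin * kernel * kernel))  # He init
        self.w = (rng.standard_normal((cout, cin, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x_shape = x.shape
        if self.kernel == 1:
            self._x = x
            return np.einsum("nchw,oc->nohw", x, self.w[:, :, 0, 0], optimize=True) + self.b[
                None, :, None, None
            ]
        out, self._xw = _conv_forward(x, self.w, self.b)
        return out

    def backward(self, dout):
        # gradients are written in place: the optimizer holds references
        if self.kernel == 1:
            self.dw[...] = np.einsum(
                "nchw,nohw->oc", self._x, dout, optimize=True
            )[:, :, None, None]
            self.db[...] = dout.sum(axis=(0, 2, 3))
            return np.einsum("nohw,oc->nchw", dout, self.w[:, :, 0, 0], optimize=True)
        dx, dw, db = _conv_backward(dout, self._xw, self.w, self._x_shape)
        self.dw[...] = dw
        self.db[...] = db
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = _Conv(cin, cout, rng), _ReLU()
        self.c2, self.r2 = _Conv(cout, cout, rng), _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def params(self):
        return self.c1.params() + self.c2.params()


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x.reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (
            (flat & first).reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        )
        return out

    def backward(self, dout):
        d = self._mask * dout[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = d.shape
        return d.reshape(n, c, h2 * 2, w2 * 2)


class _Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet2D:
    """Encoder depth ``depth`` (number of poolings), ``base`` channels at the
    top level doubling per scale, one-logit output head."""

    def __init__(self, depth: int = 3, base: int = 8, in_channels: int = 1, seed: int = 0):
        self.depth, self.base, self.in_channels = depth, base, in_channels
        rng = np.random.default_rng(seed)
        chans = [base * 2**i for i in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(_ConvBlock(cin, chans[i], rng))
            cin = chans[i]
        self.pools = [_MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[depth - 1], chans[depth], rng)
        self.ups = [_Upsample2() for _ in range(depth)]
        self.dec = []
        for i in reversed(range(depth)):
            self.dec.append(_ConvBlock(chans[i + 1] + chans[i], chans[i], rng))
        self.head = _Conv(base, 1, rng, kernel=1)

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x.astype(np.float32)
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_chans = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_chans.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = blk.forward(h)
        return self.head.forward(h)[:, 0]  # (N, H, W) logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        dskips = []
        for blk, up, (c_up, _) in zip(reversed(self.dec), reversed(self.ups),
                                      reversed(self._skip_chans)):
            d = blk.backward(d)
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        # note: after the loop, dskips[0] pairs with enc[0]'s output
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d) + dskip
            d = blk.backward(d)

    def params(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    # ------------------------------------------------------------- inference
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(x))

    # ------------------------------------------------------------------- io
    def state_dict(self) -> dict:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]

    def copy_state(self) -> dict:
        return {k: v.copy() for k, v in self.state_dict().items()}


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype) if z.dtype == np.float32 else out


def bce_dice_loss(
    logits: np.ndarray, target: np.ndarray, dice_weight: float = 0.0
) -> tuple[float, np.ndarray]:
    """Sigmoid cross-entropy (+ optional soft-Dice complement); returns
    (loss, dloss/dlogits)."""
    t = target.astype(np.float64)
    z = logits.astype(np.float64)
    p = _sigmoid(z)
    n = z.size
    # numerically stable BCE-with-logits
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dldz = (p - t) / n
    loss = bce
    if dice_weight > 0:
        eps = 1.0
        inter = float((p * t).sum())
        denom = float(p.sum() + t.sum()) + eps
        soft_dice = (2 * inter + eps) / denom
        loss += dice_weight * (1 - soft_dice)
        ds_dp = (2 * t * denom - (2 * inter + eps)) / denom**2
        dldz += dice_weight * (-ds_dp) * p * (1 - p)
    return loss, dldz.astype(np.float32)
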