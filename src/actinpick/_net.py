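"""Minimal convolutional encoder--decoder implemented in numpy.

A small U-Net-style network (stride-1 3x3 convolutions, 2x2 average
pooling, nearest-neighbour upsampling, skip connections by channel
concatenation) with hand-written backpropagation and Adam.  Everything
is float32 and driven by an explicit numpy Generator, so training is
reproducible from a seed.  The network is fully convolutional: any
input whose side is divisible by ``2**depth`` is accepted at inference.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "softmax_channels", "cross_entropy_grad", "mse_grad"]


def _conv_same(x: np.ndarray, W: np.ndarray):
    """Stride-1 same-padding convolution; returns (out, im2col matrix)."""
    B, C, H, Wd = x.shape
    O, _, k, _ = W.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    m = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * Wd, C * k * k
    )
    out = m @ W.reshape(O, -1).T
    return out.reshape(B, H, Wd, O).transpose(0, 3, 1, 2), m


class _Conv:
    """3x3 (or 1x1) convolution layer with He initialization and Adam state."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self._adam = [np.zeros_like(p) for p in (self.W, self.W, self.b, self.b)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, m = _conv_same(x, self.W)
        self._cache = (m, x.shape)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m, x_shape = self._cache
        B, C, H, Wd = x_shape
        O, _, k, _ = self.W.shape
        dm = dout.transpose(0, 2, 3, 1).reshape(B * H * Wd, O)
        self.dW = (dm.T @ m).reshape(self.W.shape)
        self.db = dout.sum(axis=(0, 2, 3))
        # full correlation: convolve dout with the flipped, transposed kernel
        W_rot = self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        dx, _ = _conv_same(dout, np.ascontiguousarray(W_rot))
        self._cache = None
        return dx

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        mW, vW, mb, vb = self._adam
        for p, g, m, v in ((self.W, self.dW, mW, vW), (self.b, self.db, mb, vb)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


def _pool2(x: np.ndarray) -> np.ndarray:
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _pool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_back(d: np.ndarray) -> np.ndarray:
    B, C, H, W = d.shape
    return d.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class UNet:
    """Symmetric encoder--decoder with skip connections.

    ``depth`` pooling levels; encoder channel widths
    ``width * 2**level``; decoder mirrors the encoder and concatenates
    the skip activation at each level; a final 1x1 convolution maps to
    ``out_channels`` logits.
    """

    def __init__(
        self,
        in_channels: int = 1,
        out_channels: int = 3,
        depth: int = 3,
        width: int = 8,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.depth = depth
        self.width = width
        rng = np.random.default_rng(seed)
        widths = [width * 2**i for i in range(depth + 1)]
        self.enc = [
            _Conv(in_channels if i == 0 else widths[i - 1], widths[i], 3, rng)
            for i in range(depth)
        ]
        self.bottleneck = _Conv(widths[depth - 1], widths[depth], 3, rng)
        self.dec = [
            _Conv(widths[i + 1] + widths[i], widths[i], 3, rng)
            for i in reversed(range(depth))
        ]
        self.head = _Conv(widths[0], out_channels, 1, rng)
        self._t = 0

    # -- graph ---------------------------------------------------------
    def layers(self) -> List[_Conv]:
        return [*self.enc, self.bottleneck, *self.dec, self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if any(s % 2**self.depth for s in x.shape[2:]):
            raise ValueError(
                f"input sides must be divisible by {2 ** self.depth}, got {x.shape[2:]}"
            )
        x = x.astype(np.float32, copy=False)
        skips = []
        masks = []
        for conv in self.enc:
            a = conv.forward(x)
            m = a > 0
            a = a * m
            skips.append(a)
            masks.append(m)
            x = _pool2(a)
        a = self.bottleneck.forward(x)
        m_bott = a > 0
        x = a * m_bott
        dec_masks = []
        for conv, skip in zip(self.dec, reversed(skips)):
            x = np.concatenate([_up2(x), skip], axis=1)
            a = conv.forward(x)
            m = a > 0
            dec_masks.append(m)
            x = a * m
        logits = self.head.forward(x)
        if train:
            self._fwd = (masks, m_bott, dec_masks)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        masks, m_bott, dec_masks = self._fwd
        d = self.head.backward(dlogits)
        dskips: List[Optional[np.ndarray]] = [None] * self.depth
        # decoder layers run deepest-first in forward, so reverse here
        for j in reversed(range(self.depth)):
            level = self.depth - 1 - j
            dcat = self.dec[j].backward(d * dec_masks[j])
            up_ch = dcat.shape[1] - self.enc[level].W.shape[0]
            d = _up2_back(dcat[:, :up_ch])
            dskips[level] = dcat[:, up_ch:]
        d = self.bottleneck.backward(d * m_bott)
        for li in reversed(range(self.depth)):
            da = _pool2_back(d) + dskips[li]
            d = self.enc[li].backward(da * masks[li])
        self._fwd = None

    def adam_step(self, lr: float) -> None:
        self._t += 1
        for layer in self.layers():
            layer.adam_step(lr, self._t)

    # -- (de)serialization --------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers()):
            out[f"W{i}"] = layer.W
            out[f"b{i}"] = layer.b
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            layer.W = np.asarray(state[f"W{i}"], dtype=np.float32)
            layer.b = np.asarray(state[f"b{i}"], dtype=np.float32)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits, targets, class_weights=None):
    """Weighted categorical cross-entropy over pixels; returns (loss, dlogits).

    ``targets`` is one-hot ``(B, C, H, W)``; per-pixel weights are the
    class weight of the true class, and the loss is weight-normalized.
    """
    p = softmax_channels(logits)
    t = targets.astype(np.float32)
    if class_weights is None:
        w_pix = np.ones(t.shape[0:1] + t.shape[2:], dtype=np.float32)
    else:
        cw = np.asarray(class_weights, dtype=np.float32)
        w_pix = (cw[None, :, None, None] * t).sum(axis=1)
    total_w = w_pix.sum()
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(w_pix * (t * logp).sum(axis=1)).sum() / total_w)
    dlogits = w_pix[:, None] * (p - t) / total_w
    return loss, dlogits.astype(np.float32)


def mse_grad(pred, targets):
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - targets.astype(np.float32)
    loss = float(np.mean(diff**2))
    return loss, (2.0 * diff / diff.size).astype(np.float32)
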