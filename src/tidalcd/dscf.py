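"""Dual-Stream Change Fusion (DSCF).

Per pyramid level the bi-temporal feature pair is fused by two branches:

* a *connection branch* — channel concatenation followed by a 3x3 and a 1x1
  convolutional block — preserving context and detail;
* a *difference branch* — a Difference-aided Attention Unit (DAU) that turns
  the signed feature difference into spatial gates (via deterministic partial
  channel exchange, depthwise-separable and wavelet convolutions) and channel
  gates (a multi-branch squeeze-excitation on the pooled difference), applies
  them to the original features, and reduces the gated concatenation with a
  depthwise-separable convolution.

The two branch outputs are combined either additively or by concatenation
followed by a single dilated 3x3 convolution (config ``fusion``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig


@dataclass
class DAUIntermediates:
    """Intermediate products of the difference branch (for inspection)."""

    fd: object
    f12: object
    f21: object
    w1: object
    w2: object
    ws: object
    fdiff: object


def channel_exchange(f1, f2):
    """Deterministic partial channel exchange at ratio 1/2.

    ``f12`` keeps the even-indexed channels of ``f1`` and takes the
    odd-indexed channels of ``f2``; ``f21`` is the complement, so the channel
    multiset of (f12, f21) equals that of (f1, f2).
    """
    if f1.shape != f2.shape:
        raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
    c = f1.shape[1]
    mask = np.zeros((1, c, 1, 1), dtype=np.float32)
    mask[:, 0::2] = 1.0
    keep, swap = nn.Tensor(mask), nn.Tensor(1.0 - mask)
    f12 = nn.add(nn.mul(f1, keep), nn.mul(f2, swap))
    f21 = nn.add(nn.mul(f2, keep), nn.mul(f1, swap))
    return f12, f21


class DSConv(nn.Module):
    """Depthwise-separable convolution block: depthwise 3x3 + pointwise 1x1."""

    def __init__(self, rng, cin, cout, bn_relu: bool = True):
        super().__init__()
        self.depthwise = nn.Conv2d(rng, cin, cin, 3, 1, 1, groups=cin)
        self.pointwise = nn.Conv2d(rng, cin, cout, 1)
        self.bn = nn.BatchNorm2d(cout) if bn_relu else None

    def forward(self, x):
        x = self.pointwise(self.depthwise(x))
        if self.bn is not None:
            x = nn.relu(self.bn(x))
        return x


class WtConv(nn.Module):
    """Shape-preserving wavelet convolution.

    One level of orthonormal Haar decomposition, a trainable depthwise 3x3
    convolution on each sub-band, and the inverse reconstruction.  Parameter
    light and strictly shape preserving.
    """

    def __init__(self, rng, c):
        super().__init__()
        self.band_conv = nn.Conv2d(rng, 4 * c, 4 * c, 3, 1, 1, groups=4 * c)

    def forward(self, x):
        return nn.haar_reconstruct(self.band_conv(nn.haar_decompose(x)))


class SELayer(nn.Module):
    """Multi-branch squeeze-excitation on the pooled difference map.

    ``k`` parallel two-layer perceptrons (reduce, ReLU, expand) applied to the
    globally average-pooled difference; their sum passes a sigmoid, yielding a
    per-channel weight vector in (0, 1).
    """

    def __init__(self, rng, c, k: int = 4, hidden: int = 8):
        super().__init__()
        h = max(hidden, 4)
        self.branches = nn.Sequential(*[
            nn.Sequential(nn.Linear(rng, c, h), nn.ReLU(),
                          nn.Linear(rng, h, c))
            for _ in range(k)])

    def forward(self, fd):
        pooled = nn.reshape(nn.global_avg_pool(fd, keepdims=False),
                            (fd.shape[0], fd.shape[1]))
        total = None
        for branch in self.branches.layers:
            out = branch(pooled)
            total = out if total is None else nn.add(total, out)
        return nn.sigmoid(total)


class DAU(nn.Module):
    """Difference-aided Attention Unit."""

    def __init__(self, rng, c, cfg: ModelConfig):
        super().__init__()
        self.abs_difference = cfg.abs_difference
        self.ds1 = DSConv(rng, 2 * c, c)
        self.wt1 = WtConv(rng, c)
        self.ds2 = DSConv(rng, 2 * c, c)
        self.wt2 = WtConv(rng, c)
        self.se = SELayer(rng, c, cfg.se_branches, cfg.se_hidden)
        self.out = DSConv(rng, 2 * c, c)

    def difference(self, f1, f2):
        fd = nn.add(f1, nn.mul(f2, -1.0))
        if self.abs_difference:
            fd = nn.add(nn.relu(fd), nn.relu(nn.mul(fd, -1.0)))
        return fd

    def forward(self, f1, f2, return_intermediates: bool = False):
        if f1.shape != f2.shape:
            raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
        fd = self.difference(f1, f2)
        f12, f21 = channel_exchange(f1, f2)
        w1 = nn.sigmoid(self.wt1(self.ds1(nn.concat([fd, f12], 1))))
        w2 = nn.sigmoid(self.wt2(self.ds2(nn.concat([fd, f21], 1))))
        ws = self.se(fd)
        ws4 = nn.reshape(ws, (ws.shape[0], ws.shape[1], 1, 1))
        g1 = nn.mul(nn.mul(ws4, w1), f1)
        g2 = nn.mul(nn.mul(ws4, w2), f2)
        fdiff = self.out(nn.concat([g1, g2], 1))
        if return_intermediates:
            return fdiff, DAUIntermediates(fd, f12, f21, w1, w2, ws, fdiff)
        return fdiff


class ConnectionBranch(nn.Module):
    """Concat -> 3x3 conv block (2C) -> 1x1 conv block (back to C)."""

    def __init__(self, rng, c):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(rng, 2 * c, 2 * c, 3, 1, 1), nn.BatchNorm2d(2 * c),
            nn.ReLU(),
            nn.Conv2d(rng, 2 * c, c, 1), nn.BatchNorm2d(c), nn.ReLU())

    def forward(self, f1, f2):
        if f1.shape != f2.shape:
            raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
        return self.block(nn.concat([f1, f2], 1))


class DSCF(nn.Module):
    """One pyramid level of dual-stream change fusion."""

    def __init__(self, rng, c, cfg: ModelConfig):
        super().__init__()
        self.connection = ConnectionBranch(rng, c)
        self.dau = DAU(rng, c, cfg)
        self.fusion = cfg.fusion
        if self.fusion == "dilated":
            self.fuse = nn.Sequential(
                nn.Conv2d(rng, 2 * c, c, 3, 1, 2, dilation=2),
                nn.BatchNorm2d(c), nn.ReLU())

    def forward(self, f1, f2):
        fcat = self.connection(f1, f2)
        fdiff = self.dau(f1, f2)
        if self.fusion == "sum":
            return nn.add(fcat, fdiff)
        return self.fuse(nn.concat([fcat, fdiff], 1))


class ConcatFuse(nn.Module):
    """Plain concatenation fusion (ablation stand-in when DSCF is disabled)."""

    def __init__(self, rng, c):
        super().__init__()
        self.block = ConnectionBranch(rng, c)

    def forward(self, f1, f2):
        return self.block(f1, f2)
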