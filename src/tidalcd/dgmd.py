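"""Deep-Guided Multiscale Decoder (DGMD) and the full change network.

The decoder derives a single-channel guidance map from the two deepest fused
levels (DFG), gates the deepest level with it, then walks the pyramid deep to
shallow: at each level a guided fusion block (DFGF) merges the current level
with the already-refined deeper output under the guidance map, and a grouped
lightweight attention block (FR) refines the result.  The four refined maps
are projected, upsampled to stride 4, summed and classified into 2-channel
full-resolution change logits.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import ImagePair, SiameseEncoder
from .config import ModelConfig
from .dscf import DSCF, ConcatFuse


class SpatialSelfAttention(nn.Module):
    """Single-head scaled dot-product attention over flattened positions."""

    def __init__(self, rng, c, dim):
        super().__init__()
        self.dim = dim
        self.q = nn.Conv2d(rng, c, dim, 1, bias=True)
        self.k = nn.Conv2d(rng, c, dim, 1, bias=True)
        self.v = nn.Conv2d(rng, c, dim, 1, bias=True)
        self.proj = nn.Conv2d(rng, dim, c, 1, bias=True)

    def forward(self, x):
        n, c, h, w = x.shape
        t = h * w

        def flat(z):  # (N, C', H, W) -> (N, T, C')
            return nn.transpose(nn.reshape(z, (n, z.shape[1], t)), (0, 2, 1))

        q, k, v = flat(self.q(x)), flat(self.k(x)), flat(self.v(x))
        attn = nn.softmax(
            nn.mul(nn.matmul(q, nn.transpose(k, (0, 2, 1))),
                   1.0 / np.sqrt(self.dim)), axis=-1)
        out = nn.matmul(attn, v)  # (N, T, dim)
        out = nn.reshape(nn.transpose(out, (0, 2, 1)), (n, self.dim, h, w))
        return self.proj(out)


class DFG(nn.Module):
    """Deep Feature Guidance: (X3, X4) -> guidance map in (0, 1) at stride 16."""

    def __init__(self, rng, c3, c4, cfg: ModelConfig):
        super().__init__()
        self.compress = nn.Sequential(nn.Conv2d(rng, c4, c3, 1),
                                      nn.BatchNorm2d(c3), nn.ReLU())
        self.conv3 = nn.Sequential(nn.Conv2d(rng, 2 * c3, c3, 3, 1, 1),
                                   nn.BatchNorm2d(c3), nn.ReLU())
        self.attention = SpatialSelfAttention(rng, c3, cfg.sa_width)
        self.head = nn.Conv2d(rng, c3, 1, 1, bias=True)

    def forward(self, x3, x4):
        if (x4.shape[2] * 2, x4.shape[3] * 2) != (x3.shape[2], x3.shape[3]):
            raise ValueError(
                f"pyramid scale mismatch: X3 {x3.shape} vs X4 {x4.shape}")
        up = nn.interpolate_bilinear(self.compress(x4),
                                     (x3.shape[2], x3.shape[3]))
        fconv = self.conv3(nn.concat([x3, up], 1))
        return nn.sigmoid(self.head(self.attention(fconv)))


class DFGF(nn.Module):
    """Deep Feature Guided Fusion of level i with the refined level i+1."""

    def __init__(self, rng, c, cfg: ModelConfig):
        super().__init__()
        r = cfg.ca_reduction
        self.expand_h = nn.Conv2d(rng, 2 * c, 2 * c, 1, bias=True)
        self.expand_l = nn.Conv2d(rng, c, 2 * c, 1, bias=True)
        self.ga = nn.Conv2d(rng, 4 * c, 2 * c, 1, bias=True)
        hidden = max(6 * c // r, 4)
        self.ca_mlp = nn.Sequential(nn.Linear(rng, 6 * c, hidden), nn.ReLU(),
                                    nn.Linear(rng, hidden, 6 * c))
        self.attn_proj = nn.Linear(rng, 6 * c, 2 * c)
        self.out = nn.Sequential(nn.Conv2d(rng, 2 * c, c, 1),
                                 nn.BatchNorm2d(c), nn.ReLU())

    def forward(self, xi, y_next, fdfg):
        n, c, h, w = xi.shape
        if y_next.shape[2:] != (h // 2, w // 2) or y_next.shape[1] != 2 * c:
            raise ValueError(
                f"refined deeper level {y_next.shape} incompatible with "
                f"level feature {xi.shape}")
        fh = self.expand_h(nn.interpolate_bilinear(y_next, (h, w)))
        fl = self.expand_l(xi)
        gate = nn.add(nn.sigmoid(nn.interpolate_bilinear(fdfg, (h, w))), 1.0)
        fga = self.ga(nn.mul(nn.concat([fh, fl], 1), gate))
        avg_h = nn.global_avg_pool(fh)   # (N, 2C, 1, 1) broadcast as global
        avg_l = nn.global_avg_pool(fl)
        ones = nn.Tensor(np.ones((1, 1, h, w), np.float32))
        fc = nn.concat([nn.mul(avg_h, ones), nn.mul(avg_l, ones), fga], 1)
        mx = nn.reshape(nn.global_max_pool(fc, keepdims=False), (n, 6 * c))
        av = nn.reshape(nn.global_avg_pool(fc, keepdims=False), (n, 6 * c))
        fca = nn.add(self.ca_mlp(mx), self.ca_mlp(av))
        a = nn.sigmoid(self.attn_proj(fca))
        a = nn.reshape(a, (n, 2 * c, 1, 1))
        fused = nn.add(nn.mul(a, fl), nn.mul(a, fh))
        return self.out(fused)


class FeatureRefine(nn.Module):
    """Lightweight grouped attention refinement (shape preserving).

    Channels split into 4 groups; each group passes a depthwise 3x3
    convolution and a channel gate (global average pool -> 1x1 -> sigmoid);
    the regrouped result is added back to the input.
    """

    GROUPS = 4

    def __init__(self, rng, c):
        super().__init__()
        if c % self.GROUPS:
            raise ValueError(
                f"channel count {c} not divisible by {self.GROUPS} groups")
        g = c // self.GROUPS
        self.group_size = g
        self.convs = nn.Sequential(*[
            nn.Conv2d(rng, g, g, 3, 1, 1, groups=g)
            for _ in range(self.GROUPS)])
        self.gates = nn.Sequential(*[
            nn.Conv2d(rng, g, g, 1, bias=True) for _ in range(self.GROUPS)])

    def forward(self, x):
        g = self.group_size
        outs = []
        for i in range(self.GROUPS):
            part = nn.narrow(x, 1, i * g, g)
            feat = self.convs.layers[i](part)
            gate = nn.sigmoid(self.gates.layers[i](nn.global_avg_pool(feat)))
            outs.append(nn.mul(feat, gate))
        return nn.add(x, nn.concat(outs, 1))


class ChangeHead(nn.Module):
    """Lightweight change map decoder (CAM).

    Each refined level is projected to a common width, bilinearly upsampled
    to stride 4, summed, passed through a 3x3 block and a 1x1 classifier, and
    upsampled x4 to full resolution 2-channel logits.
    """

    def __init__(self, rng, channels, width, num_classes=2):
        super().__init__()
        self.projs = nn.Sequential(*[
            nn.Sequential(nn.Conv2d(rng, c, width, 1), nn.BatchNorm2d(width),
                          nn.ReLU()) for c in channels])
        self.mix = nn.Sequential(nn.Conv2d(rng, width, width, 3, 1, 1),
                                 nn.BatchNorm2d(width), nn.ReLU())
        self.classifier = nn.Conv2d(rng, width, num_classes, 1, bias=True)

    def forward(self, ys):
        if len(ys) != len(self.projs.layers):
            raise ValueError(
                f"expected {len(self.projs.layers)} refined levels, "
                f"got {len(ys)}")
        target = (ys[0].shape[2], ys[0].shape[3])
        total = None
        for proj, y in zip(self.projs.layers, ys):
            p = nn.interpolate_bilinear(proj(y), target)
            total = p if total is None else nn.add(total, p)
        logits = self.classifier(self.mix(total))
        return nn.interpolate_bilinear(logits, (target[0] * 4, target[1] * 4))


class ChangeDetectionNet(nn.Module):
    """Dual-stream difference network with deep-guided multiscale decoding."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = cfg or ModelConfig()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.siamese = SiameseEncoder(rng, cfg.backbone, cfg.base_width,
                                      cfg.in_channels)
        chans = self.siamese.out_channels
        self.channels = chans
        if cfg.use_dscf:
            fuses = [DSCF(rng, c, cfg) for c in chans]
        else:
            fuses = [ConcatFuse(rng, c) for c in chans]
        self.fuse_levels = nn.Sequential(*fuses)
        if cfg.use_dfg:
            self.dfg = DFG(rng, chans[2], chans[3], cfg)
        else:
            self.dfg = None
        self.dfgf = nn.Sequential(*[DFGF(rng, c, cfg) for c in chans[:3]])
        self.refine = nn.Sequential(*[FeatureRefine(rng, c) for c in chans])
        self.head = ChangeHead(rng, chans, cfg.head_width, cfg.num_classes)

    # -- stages ------------------------------------------------------------
    def fuse_pyramids(self, p1, p2):
        return [fuse(f1, f2) for fuse, f1, f2 in
                zip(self.fuse_levels.layers, p1, p2)]

    def guidance(self, xs):
        """Guidance map at stride 16; constant 0.5 when DFG is ablated."""
        if self.dfg is not None:
            return self.dfg(xs[2], xs[3])
        n = xs[2].shape[0]
        h, w = xs[2].shape[2], xs[2].shape[3]
        return nn.Tensor(np.full((n, 1, h, w), 0.5, np.float32))

    def decode(self, xs, fdfg):
        # deepest level: gate by the guidance map, then refine
        gate4 = nn.interpolate_bilinear(fdfg, (xs[3].shape[2],
                                               xs[3].shape[3]))
        ys = [None, None, None, self.refine.layers[3](nn.mul(xs[3], gate4))]
        for i in (2, 1, 0):  # progressive deep-to-shallow decoding
            fout = self.dfgf.layers[i](xs[i], ys[i + 1], fdfg)
            ys[i] = self.refine.layers[i](fout)
        return self.head(ys)

    def forward(self, t1, t2):
        f1, f2 = self.siamese(t1, t2)
        xs = self.fuse_pyramids(f1, f2)
        return self.decode(xs, self.guidance(xs))

    def predict_pair(self, pair: ImagePair):
        """Binary change map for one (already normalized) image pair."""
        pair.validate()
        t1 = pair.t1[None] if pair.t1.ndim == 3 else pair.t1
        t2 = pair.t2[None] if pair.t2.ndim == 3 else pair.t2
        self.eval()
        with nn.no_grad():
            logits = self.forward(nn.Tensor(t1), nn.Tensor(t2))
        return logits.data.argmax(axis=1).astype(np.uint8)
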