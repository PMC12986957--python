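"""Shared-weight siamese feature extractor.

A standard 18/34-layer residual encoder (classifier head removed) taps the
four residual stages, yielding a feature pyramid at strides {4, 8, 16, 32}
with channels {64, 128, 256, 512} at the default width.  Both temporal images
pass through the *same* parameter set — the module is called twice, which is
what weight sharing means operationally.

The 50-layer bottleneck variant produces stage channels {256, ..., 2048};
they are adapted to the pyramid contract by learned 1x1 projections.  This
variant is experimental: its published complexity figure is not treated as a
hard target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class ImagePair:
    """Co-registered bi-temporal input, each (3, H, W) normalized reals."""

    t1: np.ndarray
    t2: np.ndarray

    def validate(self) -> None:
        if self.t1.shape != self.t2.shape:
            raise ValueError(
                f"t1 shape {self.t1.shape} != t2 shape {self.t2.shape}")
        h, w = self.t1.shape[-2:]
        if h % 32:
            raise ValueError(f"height {h} not divisible by 32")
        if w % 32:
            raise ValueError(f"width {w} not divisible by 32")


@dataclass
class FeaturePyramid:
    """Four feature maps at strides {4, 8, 16, 32}."""

    levels: list  # nn.Tensor, (N, C_i, H/2^{i+1}, W/2^{i+1})

    @property
    def channels(self) -> list[int]:
        return [lv.shape[1] for lv in self.levels]

    @property
    def strides(self) -> list[int]:
        return [4, 8, 16, 32]


class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, rng, cin, cout, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(rng, cin, cout, 3, stride, 1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(rng, cout, cout, 3, 1, 1)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(nn.Conv2d(rng, cin, cout, 1, stride),
                                      nn.BatchNorm2d(cout))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return nn.relu(nn.add(out, self.down(x)))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, rng, cin, cmid, stride=1):
        super().__init__()
        cout = cmid * self.expansion
        self.conv1 = nn.Conv2d(rng, cin, cmid, 1)
        self.bn1 = nn.BatchNorm2d(cmid)
        self.conv2 = nn.Conv2d(rng, cmid, cmid, 3, stride, 1)
        self.bn2 = nn.BatchNorm2d(cmid)
        self.conv3 = nn.Conv2d(rng, cmid, cout, 1)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(nn.Conv2d(rng, cin, cout, 1, stride),
                                      nn.BatchNorm2d(cout))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return nn.relu(nn.add(out, self.down(x)))


_BLOCKS = {
    "resnet18": (BasicBlock, (2, 2, 2, 2)),
    "resnet34": (BasicBlock, (3, 4, 6, 3)),
    "resnet50": (Bottleneck, (3, 4, 6, 3)),
}


class ResNetEncoder(nn.Module):
    """Four-stage residual encoder with stage taps, no classifier head."""

    def __init__(self, rng, arch: str = "resnet18", base_width: int = 64,
                 in_channels: int = 3):
        super().__init__()
        block, counts = _BLOCKS[arch]
        w = base_width
        self.arch = arch
        self.conv1 = nn.Conv2d(rng, in_channels, w, 7, 2, 3)
        self.bn1 = nn.BatchNorm2d(w)
        self.pool = nn.MaxPool2d(3, 2, 1)
        widths = [w, 2 * w, 4 * w, 8 * w]
        strides = [1, 2, 2, 2]
        cin = w
        stages = []
        for i, (cw, st, n) in enumerate(zip(widths, strides, counts)):
            blocks = []
            for b in range(n):
                blocks.append(block(rng, cin, cw, st if b == 0 else 1))
                cin = cw * block.expansion
            stages.append(nn.Sequential(*blocks))
        self.layer1, self.layer2, self.layer3, self.layer4 = stages
        self._modules.update(
            {f"layer{i + 1}": s for i, s in enumerate(stages)})
        self.stage_channels = [wi * block.expansion for wi in widths]
        # bottleneck stages are projected back to the pyramid contract
        if block.expansion != 1:
            self.projections = nn.Sequential(*[
                nn.Sequential(nn.Conv2d(rng, c, wdt, 1), nn.BatchNorm2d(wdt),
                              nn.ReLU())
                for c, wdt in zip(self.stage_channels, widths)])
            self.out_channels = widths
        else:
            self.projections = None
            self.out_channels = self.stage_channels

    def forward(self, x) -> list:
        x = self.pool(nn.relu(self.bn1(self.conv1(x))))
        feats = []
        for i, stage in enumerate(
                (self.layer1, self.layer2, self.layer3, self.layer4)):
            x = stage(x)
            feats.append(x)
        if self.projections is not None:
            feats = [proj(f) for proj, f in
                     zip(self.projections.layers, feats)]
        return feats


class SiameseEncoder(nn.Module):
    """One encoder, two temporal streams: weight sharing by construction."""

    def __init__(self, rng, arch="resnet18", base_width=64, in_channels=3):
        super().__init__()
        self.encoder = ResNetEncoder(rng, arch, base_width, in_channels)
        self.out_channels = self.encoder.out_channels

    def extract_pyramid(self, pair: ImagePair):
        pair.validate()
        t1 = pair.t1[None] if pair.t1.ndim == 3 else pair.t1
        t2 = pair.t2[None] if pair.t2.ndim == 3 else pair.t2
        p1 = FeaturePyramid(self.encoder(nn.Tensor(t1)))
        p2 = FeaturePyramid(self.encoder(nn.Tensor(t2)))
        return p1, p2

    def forward(self, x1, x2):
        return self.encoder(x1), self.encoder(x2)
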