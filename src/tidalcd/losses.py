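"""Combined focal + dice objective for imbalanced binary change detection.

Changed pixels typically make up a small fraction of a scene, so plain
cross-entropy is dominated by the unchanged background.  The focal term
down-weights easy pixels by ``(1 - p_hat)**gamma``; the dice term maximizes
soft overlap between the predicted change probability and the mask.  Two
published presets exist and disagree (``paper-methods``: alpha=0.2, gamma=2,
unit weights; ``paper-implementation``: gamma=0, alpha disabled, 0.5/0.5
weights); the default is ``paper-methods``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import LossConfig


def _validate(scores, mask) -> nn.Tensor:
    scores = nn.as_tensor(scores)
    m = mask.data if isinstance(mask, nn.Tensor) else np.asarray(mask)
    if scores.ndim != 4 or scores.shape[1] != 2:
        raise ValueError(f"scores must be (N, 2, H, W), got {scores.shape}")
    if m.shape[-2:] != scores.shape[-2:]:
        raise ValueError(
            f"mask {m.shape} not aligned with scores {scores.shape}")
    if m.size == 0:
        raise ValueError("empty image")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    y = m.reshape(scores.shape[0], 1, *scores.shape[-2:]) if m.ndim != 4 \
        else m
    return scores, nn.Tensor(y.astype(np.float32))


def change_probability(scores) -> nn.Tensor:
    """Per-pixel softmax probability of the change class, (N, 1, H, W)."""
    p = nn.softmax(scores, axis=1)
    return nn.narrow(p, 1, 1, 1)


def focal_loss(scores, mask, cfg: LossConfig | None = None) -> nn.Tensor:
    """Mean over pixels of ``-alpha * (1 - p_hat)**gamma * log(p_hat)``.

    ``p_hat`` is the predicted probability of the *true* class of each pixel;
    it is clamped to [eps, 1 - eps] before the log.  The mean (rather than
    sum) makes the loss resolution invariant.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    scores, y = _validate(scores, mask)
    p = change_probability(scores)
    p_hat = nn.add(nn.mul(y, p), nn.mul(1.0 - y, 1.0 - p))
    p_hat = nn.clip(p_hat, cfg.epsilon, 1.0 - cfg.epsilon)
    alpha = 1.0 if cfg.alpha is None else cfg.alpha
    term = nn.mul(nn.mul(nn.pow_scalar(1.0 - p_hat, cfg.gamma),
                         nn.log(p_hat)), -alpha)
    return nn.reduce_mean(term)


def dice_loss(scores, mask, cfg: LossConfig | None = None) -> nn.Tensor:
    """Soft dice on the change-class probability: 1 - 2|E.p|/(|E| + |p|)."""
    cfg = cfg or LossConfig()
    cfg.validate()
    scores, y = _validate(scores, mask)
    p = change_probability(scores)
    inter = nn.reduce_sum(nn.mul(y, p))
    total = nn.add(nn.reduce_sum(y), nn.reduce_sum(p))
    ratio = nn.mul(nn.add(nn.mul(inter, 2.0), cfg.epsilon),
                   nn.pow_scalar(nn.add(total, cfg.epsilon), -1.0))
    return nn.add(nn.mul(ratio, -1.0), 1.0)


def combined_loss(scores, mask, cfg: LossConfig | None = None) -> nn.Tensor:
    """``w_focal * L_focal + w_dice * L_dice`` (defaults: unit weights)."""
    cfg = cfg or LossConfig()
    parts = []
    if cfg.w_focal:
        parts.append(nn.mul(focal_loss(scores, mask, cfg), cfg.w_focal))
    if cfg.w_dice:
        parts.append(nn.mul(dice_loss(scores, mask, cfg), cfg.w_dice))
    if not parts:
        raise ValueError("both loss weights are zero")
    out = parts[0]
    for p in parts[1:]:
        out = nn.add(out, p)
    return out
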