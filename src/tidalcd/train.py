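"""Training, evaluation and the pixel-difference baseline.

The training recipe follows the published protocol: SGD with momentum 0.9,
weight decay 5e-5, initial learning rate 0.05 decayed 10x every 50 epochs,
combined focal+dice loss, geometric augmentation, and a fixed seed recorded
in every artifact.  The best-validation-F1 parameter set is kept.
"""

from __future__ import annotations

import json
import os
import time

import numpy as np
from PIL import Image

from . import nn
from .config import TrainConfig
from .data import BiTemporalSample, augment, normalize
from .dgmd import ChangeDetectionNet
from .losses import combined_loss
from .metrics import (ConfusionCounts, MetricSet, compute_metrics,
                      confusion_counts, render_error_map)


def prepare_batch(samples: list[BiTemporalSample], cfg: TrainConfig):
    """Stack samples into normalized (B,3,H,W) arrays plus (B,H,W) masks."""
    x1 = np.stack([normalize(s.t1, cfg.norm_mean, cfg.norm_std)
                   for s in samples])
    x2 = np.stack([normalize(s.t2, cfg.norm_mean, cfg.norm_std)
                   for s in samples])
    y = np.stack([s.mask for s in samples]).astype(np.float32)
    return x1, x2, y


def train_model(model: ChangeDetectionNet,
                train_samples: list[BiTemporalSample],
                cfg: TrainConfig,
                val_samples: list[BiTemporalSample] | None = None,
                epochs: int | None = None,
                log_path: str | None = None,
                progress: bool = False) -> dict:
    """Run the SGD loop; returns the training history.

    History holds per-epoch mean loss, the learning-rate schedule actually
    applied, validation metrics when a validation split is given, and the
    best-validation-F1 state dict under ``best_state``.
    """
    cfg.validate()
    if not train_samples:
        raise ValueError("refusing to train on an empty split")
    epochs = epochs or cfg.epochs
    rng = np.random.default_rng(cfg.seed)
    loss_cfg = _loss_cfg(cfg)
    opt = nn.SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    sched = nn.StepLR(opt, cfg.step_size, cfg.lr_decay)
    history = {"loss": [], "lr": [], "val": [], "seed": cfg.seed,
               "config_hash": cfg.config_hash(), "best_state": None,
               "best_f1": -1.0}
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, epochs + 1):
            model.train()
            order = rng.permutation(len(train_samples))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [augment(train_samples[i], cfg.augment, rng)
                         for i in idx]
                x1, x2, y = prepare_batch(batch, cfg)
                logits = model(nn.Tensor(x1), nn.Tensor(x2))
                loss = combined_loss(logits, y, loss_cfg)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"loss={float(loss.data)!r} (lr={opt.lr:g})")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            history["loss"].append(epoch_loss)
            history["lr"].append(opt.lr)
            record = {"epoch": epoch, "loss": epoch_loss, "lr": opt.lr,
                      "seed": cfg.seed, "time": time.time()}
            if val_samples:
                mset, _ = evaluate_model(model, val_samples, cfg)
                history["val"].append(mset.to_dict())
                record["val"] = mset.to_dict()
                if mset.f1 > history["best_f1"]:
                    history["best_f1"] = mset.f1
                    history["best_state"] = model.state_dict()
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if progress:
                msg = f"epoch {epoch}/{epochs} loss {epoch_loss:.4f}"
                if val_samples:
                    msg += f" val F1 {history['val'][-1]['f1']:.4f}"
                print(msg)
            sched.step()
    finally:
        if log_fh:
            log_fh.close()
    if history["best_state"] is None:
        history["best_state"] = model.state_dict()
    return history


def _loss_cfg(cfg: TrainConfig):
    from .config import loss_preset
    return loss_preset(cfg.loss_preset)


def evaluate_model(model: ChangeDetectionNet,
                   samples: list[BiTemporalSample],
                   cfg: TrainConfig,
                   per_image: bool = False,
                   error_map_dir: str | None = None,
                   batch_size: int = 8):
    """Micro-averaged metrics over a split (per-image averaging by flag).

    Predictions are the argmax over the two logit channels; no threshold.
    Returns ``(MetricSet, ConfusionCounts)``; with ``per_image`` the metric
    set is the unweighted mean of per-image metrics while the counts stay
    global.
    """
    if not samples:
        raise ValueError("refusing to evaluate an empty split")
    h, w = samples[0].mask.shape
    if h % 32 or w % 32:
        raise ValueError(f"resolution {(h, w)} not divisible by 32")
    model.eval()
    total = ConfusionCounts()
    per = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x1, x2, y = prepare_batch(chunk, cfg)
        with nn.no_grad():
            logits = model(nn.Tensor(x1), nn.Tensor(x2))
        preds = logits.data.argmax(axis=1).astype(np.uint8)
        for s, pred in zip(chunk, preds):
            c = confusion_counts(pred, s.mask)
            total = total + c
            if per_image:
                per.append(compute_metrics(c))
            if error_map_dir:
                os.makedirs(error_map_dir, exist_ok=True)
                Image.fromarray(render_error_map(pred, s.mask)).save(
                    os.path.join(error_map_dir, f"{s.id}_error.png"))
    if per_image:
        mset = MetricSet(*[float(np.mean([getattr(m, k) for m in per]))
                           for k in ("pre", "rec", "f1", "iou")])
    else:
        mset = compute_metrics(total)
    return mset, total


def metrics_report(mset: MetricSet, counts: ConfusionCounts, n_images: int,
                   seed: int) -> dict:
    """JSON-ready evaluation report."""
    rep = mset.to_dict()
    rep.update({"tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "tn": counts.tn, "n_images": n_images, "seed": seed})
    return rep


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path: str, model: ChangeDetectionNet, cfg: TrainConfig,
                    extra: dict | None = None) -> None:
    state = model.state_dict()
    meta = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
            "seed": cfg.seed, **(extra or {})}
    np.savez_compressed(path, __meta__=json.dumps(meta, default=str),
                        **state)


def load_checkpoint(path: str, model: ChangeDetectionNet) -> dict:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model.load_state_dict(state)
    return meta


# -- pixel-difference baseline ----------------------------------------------


def _difference_score(s: BiTemporalSample) -> np.ndarray:
    """Mean absolute channel difference in [0, 1]."""
    d = np.abs(s.t1.astype(np.float32) - s.t2.astype(np.float32))
    return d.mean(axis=-1) / 255.0


def fit_difference_baseline(samples: list[BiTemporalSample],
                            n_thresholds: int = 64) -> float:
    """Pick the |T1-T2| threshold maximizing F1 on the given split."""
    scores = np.concatenate([_difference_score(s).ravel() for s in samples])
    masks = np.concatenate([s.mask.ravel() for s in samples])
    best_t, best_f1 = 0.5, -1.0
    for t in np.linspace(scores.min(), scores.max(), n_thresholds + 2)[1:-1]:
        pred = (scores > t).astype(np.uint8)
        f1 = compute_metrics(confusion_counts(pred, masks)).f1
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def evaluate_difference_baseline(samples: list[BiTemporalSample],
                                 threshold: float):
    """Micro-averaged metrics of thresholded image differencing."""
    total = ConfusionCounts()
    for s in samples:
        pred = (_difference_score(s) > threshold).astype(np.uint8)
        total = total + confusion_counts(pred, s.mask)
    return compute_metrics(total), total
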