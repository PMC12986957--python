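"""Pixel-level evaluation: confusion counting, Pre/Rec/F1/IoU, error maps,
and multi-seed aggregation.

Change (1) is the positive class.  Metrics over a test split are computed
from globally accumulated confusion counts (micro-averaging), the standard
convention for change-detection benchmarks; per-image averaging is available
by flag in the evaluation driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# error-map color convention: white TP, black TN, red FP, green FN
_ERROR_COLORS = {
    "tp": (255, 255, 255),
    "tn": (0, 0, 0),
    "fp": (255, 0, 0),
    "fn": (0, 255, 0),
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricSet:
    pre: float
    rec: float
    f1: float
    iou: float

    def to_dict(self) -> dict:
        return {"precision": self.pre, "recall": self.rec, "f1": self.f1,
                "iou": self.iou}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0, 1}}")
    return arr.astype(np.int64)


def confusion_counts(pred, mask) -> ConfusionCounts:
    """Exact pixel tallies of a binary prediction against a binary mask."""
    pred = _check_binary(pred, "pred")
    mask = _check_binary(mask, "mask")
    if pred.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs mask {mask.shape}")
    tp = int(np.sum((pred == 1) & (mask == 1)))
    fp = int(np.sum((pred == 1) & (mask == 0)))
    fn = int(np.sum((pred == 0) & (mask == 1)))
    tn = int(np.sum((pred == 0) & (mask == 0)))
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Pre = TP/(TP+FP), Rec = TP/(TP+FN), F1 harmonic, IoU = TP/(TP+FP+FN).

    Degenerate conventions: if the image contains no positives at all in
    either mask or prediction (tn-only), all metrics are 1; if tp = 0 and any
    denominator vanishes otherwise, the affected metrics are 0.
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return MetricSet(1.0, 1.0, 1.0, 1.0)
    pre = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) else 0.0
    iou = c.tp / (c.tp + c.fp + c.fn)
    return MetricSet(pre, rec, f1, iou)


def f1_from_pre_rec(pre: float, rec: float) -> float:
    """Harmonic mean of precision and recall."""
    return 2 * pre * rec / (pre + rec) if (pre + rec) else 0.0


def iou_from_f1(f1: float) -> float:
    """Invert F1 = 2*IoU/(1+IoU)."""
    return f1 / (2.0 - f1)


def render_error_map(pred, mask) -> np.ndarray:
    """RGB error map: white TP, black TN, red FP, green FN."""
    pred = _check_binary(pred, "pred")
    mask = _check_binary(mask, "mask")
    if pred.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs mask {mask.shape}")
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    out[(pred == 1) & (mask == 1)] = _ERROR_COLORS["tp"]
    out[(pred == 0) & (mask == 0)] = _ERROR_COLORS["tn"]
    out[(pred == 1) & (mask == 0)] = _ERROR_COLORS["fp"]
    out[(pred == 0) & (mask == 1)] = _ERROR_COLORS["fn"]
    return out


def aggregate_runs(runs: list[MetricSet | dict],
                   seeds: list[int] | None = None) -> dict:
    """Mean +/- sample standard deviation (ddof=1) per metric over seeds."""
    if len(runs) < 2:
        raise ValueError("aggregation requires at least 2 runs")
    dicts = [r.to_dict() if isinstance(r, MetricSet) else dict(r)
             for r in runs]
    keys = dicts[0].keys()
    report = {}
    for k in keys:
        vals = np.array([d[k] for d in dicts], dtype=np.float64)
        report[k] = {"mean": float(vals.mean()),
                     "std": float(vals.std(ddof=1))}
    if seeds is not None:
        report["seeds"] = list(seeds)
    report["n_runs"] = len(runs)
    return report


def format_mean_std(report: dict, scale: float = 100.0,
                    digits: int = 2) -> str:
    """Render an aggregate report as ``metric: mean ± std`` percentage lines."""
    lines = []
    for k, v in report.items():
        if isinstance(v, dict) and "mean" in v:
            lines.append(f"{k}: {v['mean'] * scale:.{digits}f} "
                         f"± {v['std'] * scale:.{digits}f}")
    return "\n".join(lines)
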