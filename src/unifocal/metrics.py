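"""Hard evaluation metrics: DSC, IoU, recall, precision from label masks.

Metrics are computed from argmax-binarized predictions (for two-channel
softmax maps this coincides with a 0.5 threshold on the foreground channel).
A class absent from both prediction and truth has undefined metrics; such
entries are reported as NaN with a warning, never silently as 0, and are
excluded from collection averages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays import ConfusionCounts
from .errors import ContractError, InvalidLabelError

__all__ = ["MetricReport", "evaluate", "evaluate_collection", "summarize_collection"]

_METRICS = ("dsc", "iou", "recall", "precision")


@dataclass(frozen=True)
class MetricReport:
    """Per-class metric values for one image (NaN where undefined)."""

    dsc: np.ndarray
    iou: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    counts: ConfusionCounts

    @property
    def num_classes(self) -> int:
        return len(self.dsc)

    def mean(self, metric: str = "dsc") -> float:
        """Mean over classes with a defined value."""
        values = getattr(self, metric)
        if np.all(np.isnan(values)):
            return float("nan")
        return float(np.nanmean(values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": np.arange(self.num_classes),
            "dsc": self.dsc,
            "iou": self.iou,
            "recall": self.recall,
            "precision": self.precision,
        })

    def to_json(self) -> str:
        frame = self.to_frame()
        return json.dumps(
            frame.where(pd.notna(frame), None).to_dict(orient="records")
        )


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    defined = den > 0
    out[defined] = num[defined] / den[defined]
    if not np.all(defined):
        empty = np.flatnonzero(~defined)
        warnings.warn(
            f"{name} undefined for class(es) {empty.tolist()} "
            "(zero denominator); reported as NaN",
            stacklevel=3,
        )
    return out


def evaluate(pred_labels: np.ndarray, true_labels: np.ndarray,
             num_classes: int) -> MetricReport:
    """DSC, IoU, recall and precision per class for one mask pair.

    DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), recall = TP/(TP+FN),
    precision = TP/(TP+FP).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ContractError(
            f"prediction shape {pred.shape} != ground truth shape {true.shape}"
        )
    for name, mask in (("prediction", pred), ("ground truth", true)):
        if mask.min() < 0 or mask.max() >= num_classes:
            raise InvalidLabelError(
                f"{name} mask contains labels outside [0, {num_classes - 1}]"
            )
    n = pred.size
    cm = np.bincount(
        true.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)
    tp = np.diag(cm).astype(np.float64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp
    counts = ConfusionCounts(tp=tp[None, :], fp=fp[None, :], fn=fn[None, :],
                             tn=tn[None, :], mode="hard")
    return MetricReport(
        dsc=_safe_ratio(2 * tp, 2 * tp + fp + fn, "dsc"),
        iou=_safe_ratio(tp, tp + fp + fn, "iou"),
        recall=_safe_ratio(tp, tp + fn, "recall"),
        precision=_safe_ratio(tp, tp + fp, "precision"),
        counts=counts,
    )


def evaluate_collection(pred_masks, true_masks, num_classes: int) -> pd.DataFrame:
    """Per-image, per-class metrics for a collection of mask pairs.

    Returns a tidy frame with columns (image, class, dsc, iou, recall,
    precision); undefined entries are NaN.  Raw per-image values are kept so
    any downstream interval method can be applied.
    """
    rows = []
    for i, (pred, true) in enumerate(zip(pred_masks, true_masks)):
        report = evaluate(pred, true, num_classes)
        frame = report.to_frame()
        for name in ("tp", "fp", "fn", "tn"):
            frame[name] = getattr(report.counts, name)[0]
        frame.insert(0, "image", i)
        rows.append(frame)
    if not rows:
        return pd.DataFrame(columns=["image", "class", *_METRICS, "tp", "fp", "fn", "tn"])
    return pd.concat(rows, ignore_index=True)


def summarize_collection(per_image: pd.DataFrame, mode: str = "macro") -> pd.DataFrame:
    """Average per-image metrics per class.

    ``macro`` (default) averages each metric over the images where it is
    defined, matching per-image evaluation; images with an undefined value for
    a class are excluded from that mean.  ``micro`` pools confusion counts over
    all images first.  Columns: class, dsc, iou, recall, precision, n_images.
    """
    grouped = per_image.groupby("class")
    if mode == "macro":
        out = grouped[list(_METRICS)].mean()
    elif mode == "micro":
        pooled = grouped[["tp", "fp", "fn"]].sum()
        tp, fp, fn = (pooled[k].to_numpy(dtype=float) for k in ("tp", "fp", "fn"))
        out = pd.DataFrame({
            "dsc": _safe_ratio(2 * tp, 2 * tp + fp + fn, "dsc"),
            "iou": _safe_ratio(tp, tp + fp + fn, "iou"),
            "recall": _safe_ratio(tp, tp + fn, "recall"),
            "precision": _safe_ratio(tp, tp + fp, "precision"),
        }, index=pooled.index)
    else:
        raise ContractError(f"unsupported summary mode {mode!r}")
    out["n_images"] = grouped["image"].nunique()
    return out.reset_index()
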