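"""Common plumbing for loss functions: the LossValue result and shared helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _backend as B
from .arrays import clip_probabilities, validate_pair

__all__ = ["LossValue"]


@dataclass(frozen=True)
class LossValue:
    """A per-batch aggregated loss.

    ``value`` is the mean of ``per_item`` (one entry per batch item, each the
    mean over that item's spatial positions, or the class-set sum for region
    losses).  Comparable and convertible to a plain float.
    """

    value: float
    per_item: np.ndarray

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:
        return f"LossValue({self.value:.6g}, batch={len(self.per_item)})"


def prepare(p, y, epsilon: float, clip: bool = True):
    """Validate the (p, y) pair and optionally clip p for log-safety.

    Numpy inputs get the full contract check; Tensor inputs (training /
    autodiff path) only the shape check, which ``validate_pair`` handles.
    """
    if isinstance(p, B.Tensor):
        y = np.asarray(y, dtype=p.data.dtype)  # keep the model's precision
    else:
        p = np.asarray(p, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
    validate_pair(p, y)
    if clip:
        p = clip_probabilities(p, epsilon)
    return p, y


def finalize(per_item):
    """Wrap a per-item vector: LossValue for numpy, scalar Tensor for autodiff."""
    if isinstance(per_item, B.Tensor):
        return per_item.mean()
    per_item = np.asarray(per_item, dtype=np.float64)
    return LossValue(value=float(per_item.mean()), per_item=per_item)


def combine(lam: float, left, right):
    """λ·left + (1−λ)·right for LossValue or Tensor components."""
    if isinstance(left, B.Tensor) or isinstance(right, B.Tensor):
        return lam * left + (1.0 - lam) * right
    per_item = lam * left.per_item + (1.0 - lam) * right.per_item
    return LossValue(value=float(per_item.mean()), per_item=per_item)
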