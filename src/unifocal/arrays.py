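"""Shared data contracts: probability maps, one-hot labels, confusion counts.

Conventions used throughout the package:

* arrays are shaped ``(batch, *spatial, classes)`` with the **class axis last**;
* class 0 is always background; binary problems are two-channel softmax maps,
  never single-channel sigmoid maps;
* probabilities sum to one over the class axis (softmax output contract) —
  except after :func:`clip_probabilities`, which trades exact normalisation for
  log-safety.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _backend as B
from .errors import ConfigurationError, ContractError, InvalidLabelError

__all__ = [
    "one_hot_encode",
    "clip_probabilities",
    "confusion_counts",
    "ConfusionCounts",
    "validate_probability_map",
    "validate_one_hot",
    "validate_pair",
    "hard_labels",
]


def one_hot_encode(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Encode an integer label mask as one-hot channels on a new last axis.

    Parameters
    ----------
    labels
        Integer array of any shape, values in ``[0, num_classes - 1]``.
    num_classes
        Number of classes C, at least 2.

    Returns
    -------
    float array of shape ``labels.shape + (num_classes,)`` with exactly one 1
    per position.
    """
    if num_classes < 2:
        raise ConfigurationError(f"num_classes must be >= 2, got {num_classes}")
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise InvalidLabelError("label mask must contain integers")
        labels = labels.astype(np.int64)
    bad = (labels < 0) | (labels >= num_classes)
    if np.any(bad):
        offender = labels[bad].ravel()[0]
        raise InvalidLabelError(
            f"label {offender} outside valid range [0, {num_classes - 1}]"
        )
    return np.eye(num_classes, dtype=np.float64)[labels]


def clip_probabilities(p, epsilon: float = 1e-6):
    """Clamp every probability into ``[epsilon, 1 - epsilon]``.

    Guards the logarithms in the cross entropy family.  Idempotent.  Note the
    clipped map is no longer guaranteed to sum to one over the class axis.
    Accepts a numpy array or a backend Tensor.
    """
    if not 0.0 < epsilon < 0.5:
        raise ConfigurationError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    return B.clip(p, epsilon, 1.0 - epsilon)


def validate_probability_map(p: np.ndarray, atol: float = 1e-5) -> None:
    """Check the softmax-output contract: values in [0,1], channels sum to 1."""
    p = np.asarray(p)
    if p.ndim < 2 or p.shape[-1] < 2:
        raise ContractError(
            f"probability map needs shape (batch, *spatial, C>=2); got {p.shape}"
        )
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ContractError("probabilities must lie in [0, 1]")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=atol):
        worst = float(np.max(np.abs(sums - 1.0)))
        raise ContractError(
            f"class probabilities must sum to 1 (max deviation {worst:.2e} > {atol})"
        )


def validate_one_hot(y: np.ndarray) -> None:
    y = np.asarray(y)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ContractError("one-hot labels must contain only 0 and 1")
    if not np.all(y.sum(axis=-1) == 1.0):
        raise ContractError("exactly one class channel must be active per position")


def validate_pair(p, y: np.ndarray, sum_atol: float = 1e-3) -> None:
    """Cheap guard applied by every loss: matching shapes, sane probabilities.

    The channel-sum tolerance is looser than the strict softmax contract so
    that already-clipped maps remain acceptable inputs.
    """
    shape = p.shape if isinstance(p, B.Tensor) else np.asarray(p).shape
    y = np.asarray(y)
    if shape != y.shape:
        raise ContractError(
            f"probability map shape {shape} != one-hot label shape {y.shape}"
        )
    if not isinstance(p, B.Tensor):
        validate_probability_map(p, atol=sum_atol)
    validate_one_hot(y)


def hard_labels(p: np.ndarray) -> np.ndarray:
    """Argmax binarization over the class axis; ties break to the lower index."""
    return np.argmax(np.asarray(p), axis=-1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class, per-batch-item confusion counts, shape (batch, classes).

    ``soft`` counts accumulate predicted probabilities (the Tversky-index
    building blocks); ``hard`` counts accumulate argmax decisions.
    """

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    mode: str

    @property
    def num_classes(self) -> int:
        return self.tp.shape[-1]


def soft_count_terms(p, y: np.ndarray):
    """Backend-generic (tp, fp, fn) per class; used inside the region losses."""
    batch = p.shape[0]
    classes = p.shape[-1]
    pf = B.reshape(p, (batch, -1, classes))
    dtype = p.data.dtype if isinstance(p, B.Tensor) else np.asarray(p).dtype
    yf = np.asarray(y, dtype=dtype).reshape(batch, -1, classes)
    tp = B.asum(pf * yf, axis=1)
    fp = B.asum(pf * (1.0 - yf), axis=1)
    fn = B.asum((1.0 - pf) * yf, axis=1)
    return tp, fp, fn


def confusion_counts(p: np.ndarray, y: np.ndarray, mode: str = "soft") -> ConfusionCounts:
    """Per-class TP/FP/FN/TN over spatial positions.

    ``soft`` uses probability-weighted sums (tp = Σ p·g, fp = Σ p·(1−g),
    fn = Σ (1−p)·g); ``hard`` first binarizes ``p`` by argmax.
    """
    if mode not in ("soft", "hard"):
        raise ConfigurationError(f"mode must be 'soft' or 'hard', got {mode!r}")
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    validate_pair(p, y)
    if mode == "hard":
        p = one_hot_encode(hard_labels(p), p.shape[-1])
    tp, fp, fn = soft_count_terms(p, y)
    n_positions = int(np.prod(p.shape[1:-1]))
    tn = n_positions - tp - fp - fn
    if mode == "hard":
        tp, fp, fn, tn = (np.round(a) for a in (tp, fp, fn, tn))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, mode=mode)
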