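"""Region-based (Dice/Tversky-family) losses.

Region scores are computed per batch item and per class from soft confusion
counts (tp = Σ p·g, fp = Σ p·(1−g), fn = Σ (1−p)·g over spatial positions),
with an ε added to numerator and denominator so empty classes yield 1 instead
of 0/0.  A region *loss* sums ``1 − score`` over the class set (all C classes
by default, background included; ``classes="foreground"`` drops class 0) and
averages over the batch.

Tversky-side exponent convention
--------------------------------
The modified (Unified-family) Focal Tversky loss raises ``1 − mTI`` to the
power ``1 − γ`` with γ ∈ [0, 1): γ = 0 recovers the plain Tversky(δ) loss and
increasing γ *enhances* the loss of well-classified examples, complementing
the suppression on the cross entropy side.  ``literal=True`` uses exponent γ
instead (the alternative printed form), which breaks the γ = 0 reduction.

δ convention: the modified Tversky index weights the false-positive term by δ
and the false-negative term by 1 − δ, i.e. ``mTI = TI(α=δ, β=1−δ)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _backend as B
from .arrays import soft_count_terms
from .errors import ConfigurationError
from .loss_base import finalize, prepare

__all__ = [
    "RegionScore",
    "soft_dice",
    "dice_loss",
    "tversky_index",
    "tversky_loss",
    "focal_tversky_loss",
    "modified_tversky_index",
    "modified_focal_tversky_loss",
    "modified_asymmetric_focal_tversky_loss",
    "region_focal_term",
]

# Floor for (1 - score) before a fractional power: keeps the gradient finite
# at exact perfect prediction, where d/dx x^(1-γ) would blow up at x = 0.
_POW_FLOOR = 1e-12


@dataclass(frozen=True)
class RegionScore:
    """Per-class soft overlap scores, shape (batch, classes), values in [0, 1]."""

    per_class: np.ndarray

    def mean(self) -> float:
        return float(self.per_class.mean())


def _tversky_core(p, y, alpha: float, beta: float, epsilon: float):
    tp, fp, fn = soft_count_terms(p, y)
    return (tp + epsilon) / (tp + alpha * fp + beta * fn + epsilon)


def _index_result(scores):
    if isinstance(scores, B.Tensor):
        return scores
    return RegionScore(per_class=np.asarray(scores))


def _one_minus(scores, classes: str):
    lm = 1.0 - scores
    if classes == "foreground":
        lm = lm[:, 1:]
    elif classes != "all":
        raise ConfigurationError(f"classes must be 'all' or 'foreground', got {classes!r}")
    return lm


def region_focal_term(one_minus_score, exponent: float):
    """(1 − score)^exponent with a floor that keeps fractional powers finite."""
    if exponent == 1.0:
        return one_minus_score
    if exponent < 1.0:
        one_minus_score = B.clip(one_minus_score, _POW_FLOOR, 1.0)
    return B.power(one_minus_score, exponent)


def soft_dice(p, y, *, epsilon: float = 1e-6):
    """Soft Dice similarity per class: (2·tp + ε)/(2·tp + fp + fn + ε)."""
    p, y = prepare(p, y, epsilon, clip=False)
    tp, fp, fn = soft_count_terms(p, y)
    return _index_result((2.0 * tp + epsilon) / (2.0 * tp + fp + fn + epsilon))


def tversky_index(p, y, alpha: float = 0.3, beta: float = 0.7, *,
                  epsilon: float = 1e-6):
    """Tversky index per class: (tp + ε)/(tp + α·fp + β·fn + ε).

    α weights false positives, β false negatives; α = β = 0.5 is the soft
    Dice.  The common operating point is α = 0.3, β = 0.7.
    """
    if alpha < 0.0 or beta < 0.0:
        raise ConfigurationError(f"alpha/beta must be >= 0, got {alpha}, {beta}")
    p, y = prepare(p, y, epsilon, clip=False)
    return _index_result(_tversky_core(p, y, alpha, beta, epsilon))


def modified_tversky_index(p, y, delta: float = 0.6, *, epsilon: float = 1e-6):
    """Modified Tversky index: single-δ form, mTI = TI(α=δ, β=1−δ)."""
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1], got {delta}")
    return tversky_index(p, y, alpha=delta, beta=1.0 - delta, epsilon=epsilon)


def _region_loss(p, y, alpha, beta, exponent, classes, epsilon):
    p, y = prepare(p, y, epsilon, clip=False)
    scores = _tversky_core(p, y, alpha, beta, epsilon)
    lm = region_focal_term(_one_minus(scores, classes), exponent)
    return finalize(B.asum(lm, axis=1))


def dice_loss(p, y, *, classes: str = "all", epsilon: float = 1e-6):
    """Dice loss: Σ over the class set of (1 − soft Dice)."""
    return _region_loss(p, y, 0.5, 0.5, 1.0, classes, epsilon)


def tversky_loss(p, y, alpha: float = 0.3, beta: float = 0.7, *,
                 classes: str = "all", epsilon: float = 1e-6):
    """Tversky loss: Σ over the class set of (1 − TI(α, β))."""
    if alpha < 0.0 or beta < 0.0:
        raise ConfigurationError(f"alpha/beta must be >= 0, got {alpha}, {beta}")
    return _region_loss(p, y, alpha, beta, 1.0, classes, epsilon)


def focal_tversky_loss(p, y, alpha: float = 0.3, beta: float = 0.7,
                       gamma: float = 4.0 / 3.0, *, classes: str = "all",
                       epsilon: float = 1e-6):
    """Focal Tversky loss: Σ (1 − TI)^(1/γ).

    γ = 1 recovers the Tversky loss; the published optimum γ = 4/3 gives
    exponent 3/4 < 1, *enhancing* the loss of easy examples near convergence.
    """
    if gamma <= 0.0:
        raise ConfigurationError(f"gamma must be > 0, got {gamma}")
    if alpha < 0.0 or beta < 0.0:
        raise ConfigurationError(f"alpha/beta must be >= 0, got {alpha}, {beta}")
    return _region_loss(p, y, alpha, beta, 1.0 / gamma, classes, epsilon)


def _unified_gamma(gamma: float) -> float:
    if not 0.0 <= gamma < 1.0:
        raise ConfigurationError(
            f"modified/Unified Tversky losses need gamma in [0, 1), got {gamma}"
        )
    return float(gamma)


def modified_focal_tversky_loss(p, y, delta: float = 0.6, gamma: float = 0.5, *,
                                literal: bool = False, classes: str = "all",
                                epsilon: float = 1e-6):
    """Modified Focal Tversky loss: Σ (1 − mTI)^(1−γ), γ ∈ [0, 1).

    γ = 0 recovers the Tversky(δ) loss (and with δ = 0.5 the Dice loss).
    ``literal=True`` uses exponent γ instead (see module docstring).
    """
    gamma = _unified_gamma(gamma)
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1], got {delta}")
    exponent = gamma if literal else (1.0 - gamma)
    return _region_loss(p, y, delta, 1.0 - delta, exponent, classes, epsilon)


def modified_asymmetric_focal_tversky_loss(p, y, delta: float = 0.6,
                                           gamma: float = 0.5,
                                           rare_classes=(1,), *,
                                           epsilon: float = 1e-6):
    """Asymmetric modified Focal Tversky loss: enhancement only on rare classes.

    Σ_{c∉rare} (1 − mTI_c)  +  Σ_{c∈rare} (1 − mTI_c)^(1−γ); the background
    (and any non-rare class) keeps its plain Tversky term.
    """
    from .settings import validate_rare_classes

    gamma = _unified_gamma(gamma)
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1], got {delta}")
    p, y = prepare(p, y, epsilon, clip=False)
    rare = validate_rare_classes(rare_classes, num_classes=y.shape[-1])
    scores = _tversky_core(p, y, delta, 1.0 - delta, epsilon)
    lm = 1.0 - scores
    other = sorted(set(range(y.shape[-1])) - set(rare))
    rare_part = B.asum(region_focal_term(lm[:, list(rare)], 1.0 - gamma), axis=1)
    if other:
        rare_part = rare_part + B.asum(lm[:, other], axis=1)
    return finalize(rare_part)
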