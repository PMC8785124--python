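"""Cross entropy-family (distribution-based) losses.

All functions share the convention ``p_t`` = predicted probability of the true
class at each position (for one-hot y, ``p_t = Σ_c y_c p_c``), so the
categorical cross entropy per position is simply ``−log p_t``.

Per-item aggregation is the mean over spatial positions; the batch aggregate is
the mean over items.

Focal-side exponent convention
------------------------------
The modified (Unified-family) Focal loss modulates the background term by
``(1 − p_t)^γ`` with γ ∈ [0, 1).  Under this convention γ = 0 recovers the
δ-weighted cross entropy exactly, which is the reduction property the Unified
framework is built on; the enhancement exponent ``1 − γ`` lives on the Tversky
side (see :mod:`unifocal.region`).  An alternative reading modulates by
``(1 − p_t)^{1−γ}``; it is available via ``literal=True`` but breaks the γ = 0
reduction and is not used anywhere else in the package.
"""

from __future__ import annotations

import numpy as np

from . import _backend as B
from .errors import ConfigurationError
from .loss_base import finalize, prepare
from .settings import validate_rare_classes

__all__ = [
    "cross_entropy",
    "focal_loss",
    "modified_focal_loss",
    "modified_asymmetric_focal_loss",
]


def _p_true(p, y):
    """Per-position probability of the ground-truth class, shape (B, *spatial)."""
    return B.asum(p * y, axis=-1)


def cross_entropy(p, y, *, epsilon: float = 1e-6):
    """Categorical cross entropy, −(1/N) Σ_i Σ_c y_ic log p_ic per item.

    Reduces to binary cross entropy for two-channel maps.
    """
    p, y = prepare(p, y, epsilon)
    return finalize(B.mean_per_item(-B.log(_p_true(p, y))))


def _foreground_weights(y: np.ndarray, fg_weight, bg_weight) -> np.ndarray:
    """Per-position weight: fg_weight on classes >= 1, bg_weight on class 0."""
    fg = 1.0 - y[..., 0]
    return fg_weight * fg + bg_weight * (1.0 - fg)


def focal_loss(p, y, alpha=None, gamma: float = 2.0, *, epsilon: float = 1e-6):
    """Focal loss: α_t (1 − p_t)^γ · (−log p_t).

    ``alpha`` may be None (no class weighting), a scalar (applied to the
    foreground classes, with 1 − alpha on background) or a length-C vector of
    class weights.  ``gamma=0`` with ``alpha=None`` is exactly the cross
    entropy.  The published operating point is α = 0.25, γ = 2.
    """
    if gamma < 0.0:
        raise ConfigurationError(f"gamma must be >= 0, got {gamma}")
    p, y = prepare(p, y, epsilon)
    if alpha is None:
        weight = 1.0
    elif np.ndim(alpha) == 0:
        weight = _foreground_weights(y, float(alpha), 1.0 - float(alpha))
    else:
        alpha = np.asarray(alpha, dtype=np.float64)
        if alpha.shape != (y.shape[-1],):
            raise ConfigurationError(
                f"alpha vector must have length C={y.shape[-1]}, got {alpha.shape}"
            )
        weight = np.sum(alpha * y, axis=-1)
    pt = _p_true(p, y)
    term = B.power(1.0 - pt, gamma) * -B.log(pt) * weight
    return finalize(B.mean_per_item(term))


def _unified_gamma(gamma: float) -> float:
    if not 0.0 <= gamma < 1.0:
        raise ConfigurationError(
            f"modified/Unified focal losses need gamma in [0, 1), got {gamma}"
        )
    return float(gamma)


def modified_focal_loss(p, y, delta: float = 0.6, gamma: float = 0.5, *,
                        literal: bool = False, epsilon: float = 1e-6):
    """Modified Focal loss of the Unified framework: δ_t (1 − p_t)^γ (−log p_t).

    δ weights the foreground classes and 1 − δ the background, so a single
    parameter controls output imbalance.  γ = 0 recovers the δ-weighted cross
    entropy (and with δ = 0.5, half the cross entropy).  ``literal=True``
    switches the modulating exponent to 1 − γ (see module docstring).
    """
    gamma = _unified_gamma(gamma)
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1], got {delta}")
    p, y = prepare(p, y, epsilon)
    weight = _foreground_weights(y, delta, 1.0 - delta)
    exponent = (1.0 - gamma) if literal else gamma
    pt = _p_true(p, y)
    term = B.power(1.0 - pt, exponent) * -B.log(pt) * weight
    return finalize(B.mean_per_item(term))


def modified_asymmetric_focal_loss(p, y, delta: float = 0.6, gamma: float = 0.5,
                                   rare_classes=(1,), *, epsilon: float = 1e-6):
    """Asymmetric modified Focal loss: suppression spares the rare class.

    Positions whose true class is rare contribute δ·(−log p_t) unmodulated;
    all other positions contribute (1 − δ)·(1 − p_t)^γ·(−log p_t), so the
    focal suppression applies only where the easy background dominates.
    """
    gamma = _unified_gamma(gamma)
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1], got {delta}")
    p, y = prepare(p, y, epsilon)
    rare = validate_rare_classes(rare_classes, num_classes=y.shape[-1])
    rare_mask = y[..., list(rare)].sum(axis=-1)
    pt = _p_true(p, y)
    nll = -B.log(pt)
    rare_term = nll * (delta * rare_mask)
    other_term = B.power(1.0 - pt, gamma) * nll * ((1.0 - delta) * (1.0 - rare_mask))
    return finalize(B.mean_per_item(rare_term + other_term))
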