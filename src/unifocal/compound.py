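"""Compound losses: Combo, Hybrid Focal, and the Unified Focal losses.

A compound loss is a λ-weighted sum of a distribution-based component (cross
entropy family) and a region-based component (Dice/Tversky family).  The
Unified Focal loss collapses the six hyperparameters of its ancestors to three
(λ, δ, γ) — and in practice to γ alone with the recommended λ = 0.5, δ = 0.6 —
while every earlier loss in the family is recovered at a specific hyperparameter
setting.  :func:`verify_reductions` checks those reduction identities
numerically on random batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _backend as B
from .arrays import one_hot_encode, soft_count_terms
from .distribution import (
    cross_entropy,
    focal_loss,
    modified_asymmetric_focal_loss,
    modified_focal_loss,
)
from .errors import ConfigurationError
from .loss_base import combine, finalize, prepare
from .region import (
    dice_loss,
    focal_tversky_loss,
    modified_asymmetric_focal_tversky_loss,
    modified_focal_tversky_loss,
    modified_tversky_index,
    tversky_index,
    tversky_loss,
)
from .settings import LossSettings

__all__ = [
    "combo_loss",
    "hybrid_focal_loss",
    "unified_focal_symmetric",
    "unified_focal_asymmetric",
    "verify_reductions",
    "ReductionEdge",
    "ReductionReport",
]


def combo_loss(p, y, combo_alpha: float = 0.5, beta: float = 0.5, *,
               epsilon: float = 1e-6):
    """Combo loss: α·L_mCE − (1 − α)·DSC.

    The modified cross entropy term weights foreground positions by β and
    background positions by 1 − β (β > 0.5 penalises false negatives more);
    the subtracted DSC is the *foreground* soft Dice similarity (mean over
    foreground classes when C > 2 — an extension beyond the binary original).
    Because a similarity is subtracted, the range is [−(1 − α), ∞): the loss is
    negative near perfect prediction.
    """
    if not 0.0 <= combo_alpha <= 1.0:
        raise ConfigurationError(f"combo_alpha must lie in [0, 1], got {combo_alpha}")
    if not 0.0 <= beta <= 1.0:
        raise ConfigurationError(f"beta must lie in [0, 1], got {beta}")
    pc, y = prepare(p, y, epsilon)
    fg = 1.0 - y[..., 0]
    weight = beta * fg + (1.0 - beta) * (1.0 - fg)
    pt = B.asum(pc * y, axis=-1)
    mce = B.mean_per_item(-B.log(pt) * weight)

    # soft foreground Dice from unclipped probabilities
    pu, _ = prepare(p, y, epsilon, clip=False)
    tp, fp, fn = soft_count_terms(pu, y)
    dsc = (2.0 * tp + epsilon) / (2.0 * tp + fp + fn + epsilon)
    n_fg = y.shape[-1] - 1
    dsc_fg = B.asum(dsc[:, 1:], axis=1) * (1.0 / n_fg)
    return finalize(combo_alpha * mce - (1.0 - combo_alpha) * dsc_fg)


def hybrid_focal_loss(p, y, settings: LossSettings | None = None):
    """Hybrid Focal loss: λ·L_Focal + (1 − λ)·L_FocalTversky.

    Each component keeps its own hyperparameters from ``settings``: the Focal
    term uses ``alpha`` and ``focal_gamma`` (default 2), the Focal Tversky
    term uses ``(1 − beta, beta)`` and ``tversky_gamma`` (default 4/3).
    """
    s = settings if settings is not None else LossSettings(alpha=0.25, beta=0.7)
    f = focal_loss(p, y, alpha=s.alpha,
                   gamma=s.focal_gamma if s.focal_gamma is not None else 2.0,
                   epsilon=s.epsilon)
    ft = focal_tversky_loss(
        p, y, alpha=1.0 - s.beta, beta=s.beta,
        gamma=s.tversky_gamma if s.tversky_gamma is not None else 4.0 / 3.0,
        epsilon=s.epsilon)
    return combine(s.lam, f, ft)


def unified_focal_symmetric(p, y, lam: float = 0.5, delta: float = 0.6,
                            gamma: float = 0.5, *, epsilon: float = 1e-6):
    """Symmetric Unified Focal loss: λ·L_mF(δ, γ) + (1 − λ)·L_mFT(δ, γ).

    With γ = 0 and δ = 0.5 it recovers the Dice loss at λ = 0 and half the
    cross entropy at λ = 1 (the factor 1/2 comes from the δ weighting).
    Recommended heuristics: λ = 0.5, δ = 0.6, γ = 0.5.
    """
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError(f"lam must lie in [0, 1], got {lam}")
    mf = modified_focal_loss(p, y, delta=delta, gamma=gamma, epsilon=epsilon)
    mft = modified_focal_tversky_loss(p, y, delta=delta, gamma=gamma, epsilon=epsilon)
    return combine(lam, mf, mft)


def unified_focal_asymmetric(p, y, lam: float = 0.5, delta: float = 0.6,
                             gamma: float = 0.5, rare_classes=(1,), *,
                             epsilon: float = 1e-6):
    """Asymmetric Unified Focal loss: λ·L_maF + (1 − λ)·L_maFT.

    The focal parameter suppresses only non-rare cross entropy terms and
    enhances only rare-class Tversky terms, so the rare foreground never has
    its learning signal damped.
    """
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError(f"lam must lie in [0, 1], got {lam}")
    maf = modified_asymmetric_focal_loss(p, y, delta=delta, gamma=gamma,
                                         rare_classes=rare_classes, epsilon=epsilon)
    maft = modified_asymmetric_focal_tversky_loss(p, y, delta=delta, gamma=gamma,
                                                  rare_classes=rare_classes,
                                                  epsilon=epsilon)
    return combine(lam, maf, maft)


# ---------------------------------------------------------------------------
# Numeric verification of the reduction hierarchy.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionEdge:
    source: str
    target: str
    max_abs_diff: float
    passed: bool


@dataclass(frozen=True)
class ReductionReport:
    edges: tuple[ReductionEdge, ...]
    trials: int
    seed: int
    tolerance: float

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.edges)

    @property
    def max_abs_diff(self) -> float:
        return max(e.max_abs_diff for e in self.edges)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.source, e.target, e.max_abs_diff, e.passed) for e in self.edges],
            columns=["source", "target", "max_abs_diff", "passed"],
        )


def random_batch(rng: np.random.Generator, batch: int = 2,
                 shape: tuple[int, ...] = (6, 6), num_classes: int = 2):
    """A random softmax probability map and matching one-hot labels."""
    logits = rng.normal(size=(batch, *shape, num_classes))
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    p = e / e.sum(axis=-1, keepdims=True)
    labels = rng.integers(0, num_classes, size=(batch, *shape))
    return p, one_hot_encode(labels, num_classes)


def _edge_definitions():
    """(source description, target description, source fn, target fn) pairs.

    Each pair is an algebraic identity under this package's conventions; both
    sides are evaluated through their public entry points.
    """
    ce = lambda p, y: cross_entropy(p, y).value
    dice = lambda p, y: dice_loss(p, y).value
    return [
        ("Focal(gamma=0, alpha=None)", "cross entropy",
         lambda p, y: focal_loss(p, y, alpha=None, gamma=0.0).value, ce),
        ("FocalTversky(gamma=1)", "Tversky(0.3, 0.7)",
         lambda p, y: focal_tversky_loss(p, y, 0.3, 0.7, gamma=1.0).value,
         lambda p, y: tversky_loss(p, y, 0.3, 0.7).value),
        ("Tversky(0.5, 0.5)", "Dice",
         lambda p, y: tversky_loss(p, y, 0.5, 0.5).value, dice),
        ("mTI(delta=0.6)", "TI(0.6, 0.4)",
         lambda p, y: float(modified_tversky_index(p, y, 0.6).per_class.sum()),
         lambda p, y: float(tversky_index(p, y, 0.6, 0.4).per_class.sum())),
        ("UF_sym(lam=1, gamma=0, delta=0.5)", "0.5 * cross entropy",
         lambda p, y: unified_focal_symmetric(p, y, 1.0, 0.5, 0.0).value,
         lambda p, y: 0.5 * ce(p, y)),
        ("UF_sym(lam=0, gamma=0, delta=0.5)", "Dice",
         lambda p, y: unified_focal_symmetric(p, y, 0.0, 0.5, 0.0).value, dice),
        ("UF_sym(lam=1)", "modified Focal(0.6, 0.5)",
         lambda p, y: unified_focal_symmetric(p, y, 1.0, 0.6, 0.5).value,
         lambda p, y: modified_focal_loss(p, y, 0.6, 0.5).value),
        ("UF_sym(lam=0)", "modified Focal Tversky(0.6, 0.5)",
         lambda p, y: unified_focal_symmetric(p, y, 0.0, 0.6, 0.5).value,
         lambda p, y: modified_focal_tversky_loss(p, y, 0.6, 0.5).value),
        ("UF_asym(lam=1)", "modified asymmetric Focal(0.6, 0.5)",
         lambda p, y: unified_focal_asymmetric(p, y, 1.0, 0.6, 0.5).value,
         lambda p, y: modified_asymmetric_focal_loss(p, y, 0.6, 0.5).value),
        ("UF_asym(lam=0)", "modified asymmetric Focal Tversky(0.6, 0.5)",
         lambda p, y: unified_focal_asymmetric(p, y, 0.0, 0.6, 0.5).value,
         lambda p, y: modified_asymmetric_focal_tversky_loss(p, y, 0.6, 0.5).value),
        ("UF_asym(gamma=0)", "UF_sym(gamma=0)  [C=2, rare={1}]",
         lambda p, y: unified_focal_asymmetric(p, y, 0.5, 0.6, 0.0).value,
         lambda p, y: unified_focal_symmetric(p, y, 0.5, 0.6, 0.0).value),
        ("Hybrid(lam=1)", "Focal(0.25, 2)",
         lambda p, y: hybrid_focal_loss(p, y, LossSettings(alpha=0.25, lam=1.0)).value,
         lambda p, y: focal_loss(p, y, alpha=0.25, gamma=2.0).value),
        ("Hybrid(lam=0)", "FocalTversky(0.3, 0.7, 4/3)",
         lambda p, y: hybrid_focal_loss(p, y, LossSettings(alpha=0.25, lam=0.0)).value,
         lambda p, y: focal_tversky_loss(p, y, 0.3, 0.7, 4.0 / 3.0).value),
    ]


def verify_reductions(trials: int = 100, seed: int = 17,
                      tolerance: float = 1e-6) -> ReductionReport:
    """Evaluate every reduction edge on random batches and report max |diff|.

    Each edge states that one loss at a specific hyperparameter setting equals
    another loss; both sides are evaluated on ``trials`` seeded random (p, y)
    batches (binary, 2x6x6) and the maximum absolute difference is recorded.
    """
    if trials < 1:
        raise ConfigurationError(f"trials must be >= 1, got {trials}")
    rng = np.random.default_rng(seed)
    batches = [random_batch(rng) for _ in range(trials)]
    edges = []
    for source, target, f_src, f_tgt in _edge_definitions():
        diff = max(abs(f_src(p, y) - f_tgt(p, y)) for p, y in batches)
        edges.append(ReductionEdge(source, target, float(diff), diff < tolerance))
    return ReductionReport(tuple(edges), trials, seed, tolerance)
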