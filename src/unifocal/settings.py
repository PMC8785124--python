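"""Hyperparameter container shared by the compound losses and the harness."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

__all__ = ["LossSettings", "validate_rare_classes"]


def validate_rare_classes(rare_classes, num_classes: int | None = None) -> tuple[int, ...]:
    """Rare classes must be a nonempty subset of the foreground classes {1..C-1}."""
    rare = tuple(sorted(set(int(c) for c in rare_classes)))
    if not rare:
        raise ConfigurationError("rare_classes must be nonempty")
    if any(c < 1 for c in rare):
        raise ConfigurationError(
            f"rare_classes may not include the background class 0: {rare}"
        )
    if num_classes is not None and any(c >= num_classes for c in rare):
        raise ConfigurationError(
            f"rare class index out of range for C={num_classes}: {rare}"
        )
    return rare


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class LossSettings:
    """All loss hyperparameters in one place.

    Defaults follow the recommended heuristics for the Unified Focal losses:
    λ = 0.5 (equal weight to the distribution and region components), δ = 0.6
    (weights the rare-class cross entropy term and skews the Tversky index),
    γ = 0.5 (mid-range focal parameter, stable across tasks).

    ``focal_gamma`` / ``tversky_gamma`` optionally override ``gamma`` for the
    Hybrid Focal components, whose published operating points differ
    (γ = 2 for the Focal term, γ = 4/3 for the Focal Tversky term).
    """

    alpha: float | None = None          # Focal loss class weight (optional)
    gamma: float = 0.5                  # focal parameter
    beta: float = 0.7                   # Tversky / Combo false-negative weight
    delta: float = 0.6                  # Unified output-imbalance weight
    lam: float = 0.5                    # compound mixing weight λ
    epsilon: float = 1e-6               # smoothing / clipping constant
    rare_classes: tuple[int, ...] = (1,)
    aggregation: str = "mean-over-batch"
    combo_alpha: float = 0.5            # Combo mixing weight
    focal_gamma: float | None = None    # Hybrid: Focal-component γ (default 2)
    tversky_gamma: float | None = None  # Hybrid: Focal-Tversky-component γ (default 4/3)

    def __post_init__(self):
        for name in ("beta", "delta", "lam", "combo_alpha"):
            _check_unit(name, getattr(self, name))
        if self.gamma < 0.0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 < self.epsilon < 0.5:
            raise ConfigurationError(f"epsilon must lie in (0, 0.5), got {self.epsilon}")
        if self.aggregation != "mean-over-batch":
            raise ConfigurationError(
                f"unsupported aggregation {self.aggregation!r}"
            )
        validate_rare_classes(self.rare_classes)

    def require_unified_gamma(self) -> float:
        """The modified/Unified losses need γ ∈ [0, 1) so 1−γ stays positive."""
        if not 0.0 <= self.gamma < 1.0:
            raise ConfigurationError(
                f"Unified/modified losses need gamma in [0, 1), got {self.gamma}"
            )
        return self.gamma

    def with_(self, **changes) -> "LossSettings":
        return replace(self, **changes)
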