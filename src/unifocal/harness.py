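"""Desk-scale experiments: loss landscapes, γ-stability sweeps, benchmarks.

The harness compares the losses end-to-end on synthetic imbalanced tasks with
the tiny segmenter from :mod:`unifocal.model`.  It produces:

* :func:`loss_landscape` — per-position / per-class loss terms as a function of
  ``p_t`` (cross entropy family) or the (modified) Tversky index (region
  family), exported as tidy rows;
* :func:`gamma_sweep` — trains the Unified Focal losses across a γ grid and
  reports test metrics per γ (a stability check of the single remaining
  hyperparameter);
* :func:`run_benchmark` — trains one model per (loss, seed) and evaluates hard
  metrics on the test split.

Stochastic comparisons are made over seed ensembles, never single runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compound, distribution, region
from .errors import ConfigurationError
from .metrics import evaluate_collection, summarize_collection
from .model import ModelSpec, TinyConvSegmenter, TrainingHistory, train_model
from .settings import LossSettings
from .synthetic import SyntheticTask

__all__ = [
    "LOSS_REGISTRY",
    "make_loss",
    "loss_landscape",
    "gamma_sweep",
    "run_benchmark",
    "BenchmarkResult",
    "results_to_frame",
]


def make_loss(name: str, settings: LossSettings | None = None):
    """Resolve a loss by registry name into a ``loss_fn(p, y)`` callable."""
    s = settings if settings is not None else LossSettings()
    try:
        factory = LOSS_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown loss {name!r}; available: {sorted(LOSS_REGISTRY)}"
        ) from None
    return factory(s)


LOSS_REGISTRY = {
    "cross_entropy": lambda s: lambda p, y: distribution.cross_entropy(
        p, y, epsilon=s.epsilon),
    "focal": lambda s: lambda p, y: distribution.focal_loss(
        p, y, alpha=s.alpha if s.alpha is not None else 0.25,
        gamma=s.focal_gamma if s.focal_gamma is not None else 2.0,
        epsilon=s.epsilon),
    "dice": lambda s: lambda p, y: region.dice_loss(p, y, epsilon=s.epsilon),
    "tversky": lambda s: lambda p, y: region.tversky_loss(
        p, y, alpha=1.0 - s.beta, beta=s.beta, epsilon=s.epsilon),
    "focal_tversky": lambda s: lambda p, y: region.focal_tversky_loss(
        p, y, alpha=1.0 - s.beta, beta=s.beta,
        gamma=s.tversky_gamma if s.tversky_gamma is not None else 4.0 / 3.0,
        epsilon=s.epsilon),
    "combo": lambda s: lambda p, y: compound.combo_loss(
        p, y, combo_alpha=s.combo_alpha, beta=s.beta, epsilon=s.epsilon),
    "hybrid_focal": lambda s: lambda p, y: compound.hybrid_focal_loss(p, y, s),
    "unified_focal_sym": lambda s: lambda p, y: compound.unified_focal_symmetric(
        p, y, lam=s.lam, delta=s.delta, gamma=s.gamma, epsilon=s.epsilon),
    "unified_focal_asym": lambda s: lambda p, y: compound.unified_focal_asymmetric(
        p, y, lam=s.lam, delta=s.delta, gamma=s.gamma,
        rare_classes=s.rare_classes, epsilon=s.epsilon),
}


# ---------------------------------------------------------------------------
# Loss landscape (loss value vs p_t or vs Tversky index)
# ---------------------------------------------------------------------------

def _single_pixel_batch(p_t: float, true_class: int):
    """A one-position binary batch whose ground-truth probability is p_t."""
    if true_class == 1:
        p = np.array([[[1.0 - p_t, p_t]]])
        y = np.array([[[0.0, 1.0]]])
    else:
        p = np.array([[[p_t, 1.0 - p_t]]])
        y = np.array([[[1.0, 0.0]]])
    return p, y


_CE_FAMILY = {
    "cross_entropy": lambda p, y, s: distribution.cross_entropy(p, y).value,
    "focal": lambda p, y, s: distribution.focal_loss(
        p, y, alpha=s.alpha, gamma=s.focal_gamma if s.focal_gamma is not None else 2.0).value,
    "modified_focal": lambda p, y, s: distribution.modified_focal_loss(
        p, y, delta=s.delta, gamma=s.gamma).value,
    "modified_asymmetric_focal": lambda p, y, s:
        distribution.modified_asymmetric_focal_loss(
            p, y, delta=s.delta, gamma=s.gamma, rare_classes=s.rare_classes).value,
}

_REGION_EXPONENT = {
    "tversky": lambda s: 1.0,
    "focal_tversky": lambda s: 1.0 / (s.tversky_gamma if s.tversky_gamma is not None else 4.0 / 3.0),
    "modified_focal_tversky": lambda s: 1.0 - s.gamma,
    "modified_asymmetric_focal_tversky_rare": lambda s: 1.0 - s.gamma,
}


def loss_landscape(losses, grid_size: int = 200,
                   true_class: int = 1) -> pd.DataFrame:
    """Evaluate per-position / per-class loss terms over a uniform grid.

    ``losses`` is a list of ``(name, LossSettings)`` pairs.  Cross
    entropy-family names are evaluated on single-pixel batches as a function
    of ``p_t``; region-family names as the transformed term
    ``(1 − TI)^exponent`` as a function of the (modified) Tversky index.
    Returns tidy rows (loss, abscissa_type, abscissa, value).
    """
    if grid_size < 10:
        raise ConfigurationError("grid_size must be >= 10")
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]  # open interval (0, 1)
    rows = []
    for name, settings in losses:
        s = settings if settings is not None else LossSettings()
        if name in _CE_FAMILY:
            fn = _CE_FAMILY[name]
            for p_t in grid:
                p, y = _single_pixel_batch(float(p_t), true_class)
                rows.append((name, "p_t", float(p_t), float(fn(p, y, s))))
        elif name in _REGION_EXPONENT:
            exponent = _REGION_EXPONENT[name](s)
            for ti in grid:
                value = float(region.region_focal_term(
                    np.array(1.0 - ti), exponent))
                rows.append((name, "mTI", float(ti), value))
        else:
            raise ConfigurationError(f"no landscape family for loss {name!r}")
    return pd.DataFrame(rows, columns=["loss", "abscissa_type", "abscissa", "value"])


# ---------------------------------------------------------------------------
# Training benchmarks
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Outcome of one (loss, seed) training run on a synthetic task."""

    loss_name: str
    settings: LossSettings
    seed: int
    metrics: pd.DataFrame          # per-class test metrics (class, dsc, iou, ...)
    history: TrainingHistory
    wall_time: float
    failed: bool = False
    failure_reason: str = ""

    def metric(self, name: str, class_index: int) -> float:
        row = self.metrics[self.metrics["class"] == class_index]
        return float(row[name].iloc[0]) if len(row) else float("nan")


def _run_one(loss_name: str, settings: LossSettings, seed: int,
             train: SyntheticTask, val: SyntheticTask, test: SyntheticTask,
             model_spec: ModelSpec) -> BenchmarkResult:
    start = time.perf_counter()
    loss_fn = make_loss(loss_name, settings)
    model = TinyConvSegmenter(train.spec["num_classes"], model_spec, seed=seed)
    history = train_model(model, train.images, train.masks, loss_fn, seed=seed,
                          val_images=val.images, val_masks=val.masks)
    preds = model.predict(test.images)
    per_image = evaluate_collection(list(preds), list(test.masks),
                                    train.spec["num_classes"])
    summary = summarize_collection(per_image)
    return BenchmarkResult(
        loss_name=loss_name, settings=settings, seed=seed, metrics=summary,
        history=history, wall_time=time.perf_counter() - start,
        failed=history.diverged,
        failure_reason="training loss became non-finite" if history.diverged else "",
    )


def run_benchmark(losses, task_splits, model_spec: ModelSpec = ModelSpec(),
                  seeds=(0,)) -> list[BenchmarkResult]:
    """Train and evaluate every (loss, seed) combination.

    ``losses`` is a list of ``(name, LossSettings)``; ``task_splits`` is the
    (train, val, test) triple from :func:`unifocal.synthetic.split`.  A run
    whose training diverges is flagged failed; the benchmark continues.
    """
    train, val, test = task_splits
    results = []
    for name, settings in losses:
        for seed in seeds:
            results.append(_run_one(name, settings or LossSettings(), seed,
                                    train, val, test, model_spec))
    return results


def gamma_sweep(gammas, task_splits, model_spec: ModelSpec = ModelSpec(),
                seeds=(0,), variants=("sym", "asym")) -> list[BenchmarkResult]:
    """Train the Unified Focal losses over a γ grid (both variants by default).

    Returns one BenchmarkResult per (γ, variant, seed); an empty γ list yields
    an empty result.  This is the stability analogue of tuning the single
    remaining hyperparameter: across a sensible γ range no run should diverge
    and test DSC should stay flat.
    """
    losses = []
    for gamma in gammas:
        for variant in variants:
            name = f"unified_focal_{variant}"
            losses.append((name, LossSettings(gamma=float(gamma))))
    return run_benchmark(losses, task_splits, model_spec, seeds)


def results_to_frame(results) -> pd.DataFrame:
    """Flatten BenchmarkResults to one row per (run, class)."""
    rows = []
    for r in results:
        for _, m in r.metrics.iterrows():
            rows.append({
                "loss": r.loss_name, "seed": r.seed, "gamma": r.settings.gamma,
                "class": int(m["class"]), "dsc": m["dsc"], "iou": m["iou"],
                "recall": m["recall"], "precision": m["precision"],
                "epochs_run": r.history.epochs_run,
                "final_train_loss": r.history.final_train_loss,
                "wall_time": r.wall_time, "failed": r.failed,
            })
    return pd.DataFrame(rows)
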