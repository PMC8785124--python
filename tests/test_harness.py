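import warnings

import numpy as np
import pytest

import unifocal as uf
from unifocal.errors import ConfigurationError
from unifocal.harness import (
    LOSS_REGISTRY,
    gamma_sweep,
    loss_landscape,
    make_loss,
    results_to_frame,
    run_benchmark,
)
from unifocal.model import ModelSpec, TinyConvSegmenter, train_model
from unifocal.settings import LossSettings


@pytest.fixture(scope="module")
def easy_splits():
    """High-contrast, low-noise 10% foreground task: every loss should solve it."""
    task = uf.generate(n_images=60, shape=(48, 48), target_fraction=0.10,
                       seed=11, noise_sd=0.1, contrast=1.0)
    return uf.split(task, seed=11)


class TestLossLandscape:
    def test_ce_family_curves_non_increasing_in_pt(self):
        frame = loss_landscape(
            [("cross_entropy", None), ("modified_focal", None), ("focal", None)],
            grid_size=50)
        for name, group in frame.groupby("loss"):
            values = group.sort_values("abscissa")["value"].to_numpy()
            assert np.all(np.diff(values) <= 1e-12), name
            assert values[-1] < 0.05  # vanishes as p_t -> 1
            assert np.all(np.isfinite(values))

    def test_region_family_curves_non_decreasing_in_one_minus_ti(self):
        frame = loss_landscape(
            [("tversky", None), ("focal_tversky", None),
             ("modified_focal_tversky", None)], grid_size=50)
        for name, group in frame.groupby("loss"):
            values = group.sort_values("abscissa", ascending=False)["value"].to_numpy()
            assert np.all(np.diff(values) >= -1e-12), name

    def test_background_modified_focal_term_decreases_with_gamma(self):
        # at fixed p_t = 0.5, delta fixed: value = (1-delta) * 0.5^gamma * ln 2
        values = []
        for gamma in np.arange(0.1, 1.0, 0.1):
            frame = loss_landscape(
                [("modified_focal", LossSettings(gamma=gamma))],
                grid_size=49, true_class=0)
            mid = frame.iloc[(frame["abscissa"] - 0.5).abs().argmin()]
            values.append(mid["value"])
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_focal_tversky_fixture_row_present(self):
        frame = loss_landscape([("focal_tversky", None)], grid_size=98)
        row = frame.iloc[(frame["abscissa"] - 0.75).abs().argmin()]
        assert row["value"] == pytest.approx(0.25 ** 0.75, abs=1e-2)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            loss_landscape([("no_such_loss", None)])


class TestBenchmark:
    def test_every_loss_solves_the_easy_task(self, easy_splits):
        losses = [(name, None) for name in sorted(LOSS_REGISTRY)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark(losses, easy_splits, ModelSpec(epochs=8),
                                    seeds=[0])
        frame = results_to_frame(results)
        fg = frame[frame["class"] == 1]
        assert not fg["failed"].any()
        assert (fg["dsc"] >= 0.90).all(), fg[["loss", "dsc"]]

    def test_zero_epoch_budget_returns_untrained_metrics(self, easy_splits):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark([("dice", None)], easy_splits,
                                    ModelSpec(epochs=0), seeds=[0])
        assert len(results) == 1
        assert results[0].history.epochs_run == 0
        assert not results[0].failed
        assert len(results[0].metrics) == 2

    def test_reproducible_given_seed(self, easy_splits):
        spec = ModelSpec(epochs=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_benchmark([("unified_focal_asym", None)], easy_splits, spec,
                              seeds=[3])[0]
            b = run_benchmark([("unified_focal_asym", None)], easy_splits, spec,
                              seeds=[3])[0]
        assert a.metrics.equals(b.metrics)
        assert a.history.train_losses == b.history.train_losses

    def test_unknown_loss_name_rejected(self):
        with pytest.raises(ConfigurationError):
            make_loss("not_a_loss")


class TestGammaSweep:
    def test_empty_gamma_list_is_vacuous(self, easy_splits):
        assert gamma_sweep([], easy_splits) == []

    def test_sweep_runs_both_variants_per_gamma(self, easy_splits):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = gamma_sweep([0.2, 0.8], easy_splits, ModelSpec(epochs=1),
                                  seeds=[0])
        assert len(results) == 4
        assert {r.loss_name for r in results} == {"unified_focal_sym",
                                                  "unified_focal_asym"}
        assert not any(r.failed for r in results)

    def test_sweep_gamma_matches_standalone_run(self, easy_splits):
        spec = ModelSpec(epochs=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            swept = gamma_sweep([0.5], easy_splits, spec, seeds=[0],
                                variants=("asym",))[0]
            alone = run_benchmark([("unified_focal_asym",
                                    LossSettings(gamma=0.5))], easy_splits,
                                  spec, seeds=[0])[0]
        assert swept.metrics.equals(alone.metrics)


class TestModel:
    def test_parameter_count_is_desk_scale(self):
        model = TinyConvSegmenter(2, ModelSpec(), seed=0)
        assert model.n_parameters <= 100_000

    def test_probability_output_contract(self, easy_splits):
        train, _, _ = easy_splits
        model = TinyConvSegmenter(2, ModelSpec(), seed=0)
        p = model.predict_proba(train.images[:2])
        assert p.shape == (2, 48, 48, 2)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_training_reduces_loss(self, easy_splits):
        train, val, _ = easy_splits
        model = TinyConvSegmenter(2, ModelSpec(epochs=5), seed=0)
        history = train_model(model, train.images, train.masks,
                              make_loss("dice"), seed=0,
                              val_images=val.images, val_masks=val.masks)
        assert history.train_losses[-1] < history.train_losses[0]
        assert not history.diverged
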