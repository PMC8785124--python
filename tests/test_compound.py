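import numpy as np
import pytest

import oracles
import unifocal as uf
from conftest import make_random_batch
from unifocal.errors import ConfigurationError
from unifocal.settings import LossSettings


class TestComboLoss:
    def test_perfect_prediction_attains_lower_bound(self):
        y = uf.one_hot_encode(np.array([[0, 1], [1, 1]])[None], 2)
        value = uf.combo_loss(y, y, combo_alpha=0.5, beta=0.5).value
        assert value == pytest.approx(-0.5, abs=1e-4)

    def test_symmetric_beta_halves_cross_entropy_term(self, random_batch):
        p, y = random_batch
        combo_full = uf.combo_loss(p, y, combo_alpha=1.0, beta=0.5).value
        assert combo_full == pytest.approx(0.5 * uf.cross_entropy(p, y).value,
                                           abs=1e-9)

    def test_alpha_one_is_weighted_cross_entropy_only(self, rng):
        p, y = make_random_batch(rng)
        got = uf.combo_loss(p, y, combo_alpha=1.0, beta=0.7).value
        want = oracles.combo_item(p[0], y[0], 1.0, 0.7) / 2 + \
            oracles.combo_item(p[1], y[1], 1.0, 0.7) / 2
        assert got == pytest.approx(want, abs=1e-9)

    def test_lower_bound_respected(self, rng):
        for _ in range(20):
            p, y = make_random_batch(rng)
            assert uf.combo_loss(p, y, 0.3, 0.5).value >= -(1 - 0.3) - 1e-9

    def test_out_of_range_parameters_rejected(self, random_batch):
        p, y = random_batch
        with pytest.raises(ConfigurationError):
            uf.combo_loss(p, y, combo_alpha=1.2)


class TestHybridFocalLoss:
    def test_lambda_boundaries(self, random_batch):
        p, y = random_batch
        s = LossSettings(alpha=0.25)
        assert uf.hybrid_focal_loss(p, y, s.with_(lam=1.0)).value == pytest.approx(
            uf.focal_loss(p, y, 0.25, 2.0).value, abs=1e-12)
        assert uf.hybrid_focal_loss(p, y, s.with_(lam=0.0)).value == pytest.approx(
            uf.focal_tversky_loss(p, y, 0.3, 0.7, 4 / 3).value, abs=1e-12)

    def test_midpoint_is_component_mean(self, rng):
        p, y = make_random_batch(rng)
        s = LossSettings(alpha=0.25, lam=0.5)
        f = uf.focal_loss(p, y, 0.25, 2.0).value
        ft = uf.focal_tversky_loss(p, y, 0.3, 0.7, 4 / 3).value
        assert uf.hybrid_focal_loss(p, y, s).value == pytest.approx(
            (f + ft) / 2, abs=1e-12)


class TestUnifiedFocalLosses:
    def test_symmetric_recovers_dice_and_half_cross_entropy(self, rng):
        for _ in range(100):
            p, y = make_random_batch(rng)
            assert abs(uf.unified_focal_symmetric(p, y, 0.0, 0.5, 0.0).value
                       - uf.dice_loss(p, y).value) < 1e-6
            assert abs(uf.unified_focal_symmetric(p, y, 1.0, 0.5, 0.0).value
                       - 0.5 * uf.cross_entropy(p, y).value) < 1e-6

    def test_default_heuristics_match_component_oracle(self, rng):
        p, y = make_random_batch(rng)
        got = uf.unified_focal_symmetric(p, y, 0.5, 0.6, 0.5).value
        want = np.mean([oracles.unified_sym_item(p[i], y[i], 0.5, 0.6, 0.5)
                        for i in range(2)])
        assert got == pytest.approx(want, abs=1e-9)

    def test_asymmetric_gamma_zero_collapses_to_symmetric(self, rng):
        for _ in range(30):
            p, y = make_random_batch(rng)
            diff = abs(uf.unified_focal_asymmetric(p, y, 0.5, 0.6, 0.0).value
                       - uf.unified_focal_symmetric(p, y, 0.5, 0.6, 0.0).value)
            assert diff < 1e-9

    def test_asymmetric_composite_fixture(self):
        # lam=0.5 mix of the hand-derived distribution (0.3059) and
        # region (0.9292) components on their two-position/two-class fixtures
        p_dist = np.array([[[0.5, 0.5], [0.5, 0.5]]])
        y_dist = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        maf = uf.modified_asymmetric_focal_loss(p_dist, y_dist, 0.6, 0.5).value
        from unifocal.region import region_focal_term

        maft = 0.1 + float(region_focal_term(np.array(0.6875), 0.5))
        assert 0.5 * maf + 0.5 * maft == pytest.approx(0.6176, abs=1e-4)

    def test_affine_in_lambda(self, rng):
        p, y = make_random_batch(rng)
        for loss, kwargs in [
            (uf.unified_focal_symmetric, {}),
            (uf.unified_focal_asymmetric, {"rare_classes": (1,)}),
        ]:
            a = loss(p, y, 1.0, 0.6, 0.5, **kwargs).value
            b = loss(p, y, 0.0, 0.6, 0.5, **kwargs).value
            for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
                got = loss(p, y, lam, 0.6, 0.5, **kwargs).value
                assert got == pytest.approx(lam * a + (1 - lam) * b, abs=1e-12)

    def test_loss_decreases_along_path_to_truth(self, rng):
        p0, y = make_random_batch(rng, shape=(6, 6))
        values = []
        for t in (0.0, 0.25, 0.5, 0.75, 1.0):
            p = (1 - t) * p0 + t * y
            values.append(uf.unified_focal_asymmetric(p, y).value)
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == min(values)

    def test_oracle_agreement(self, rng):
        for _ in range(20):
            p, y = make_random_batch(rng)
            got = uf.unified_focal_asymmetric(p, y, 0.5, 0.6, 0.5).value
            want = np.mean([oracles.unified_asym_item(p[i], y[i], 0.5, 0.6, 0.5, {1})
                            for i in range(2)])
            assert got == pytest.approx(want, abs=1e-9)


class TestVerifyReductions:
    def test_all_textual_edges_pass(self):
        report = uf.verify_reductions(trials=30, seed=17, tolerance=1e-6)
        assert report.all_passed
        assert report.max_abs_diff < 1e-6
        sources = [e.source for e in report.edges]
        assert any("Focal(gamma=0" in s for s in sources)
        assert any("Tversky(0.5, 0.5)" in s for s in sources)

    def test_trivial_single_perfect_trial(self):
        report = uf.verify_reductions(trials=1, seed=0, tolerance=1e-4)
        assert report.all_passed

    def test_negative_control_missets_an_edge(self):
        # gamma=0.3 Focal loss is NOT the cross entropy: the same comparison
        # machinery must flag it.
        from unifocal.compound import random_batch as rb

        rng = np.random.default_rng(17)
        diffs = [abs(uf.focal_loss(p, y, None, 0.3).value
                     - uf.cross_entropy(p, y).value)
                 for p, y in (rb(rng) for _ in range(10))]
        assert max(diffs) > 1e-6

    def test_report_frame_shape(self):
        report = uf.verify_reductions(trials=2, seed=1)
        frame = report.to_frame()
        assert set(frame.columns) == {"source", "target", "max_abs_diff", "passed"}
        assert len(frame) == len(report.edges)
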