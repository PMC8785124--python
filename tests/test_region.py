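import numpy as np
import pytest

import oracles
import unifocal as uf
from conftest import make_random_batch
from unifocal.errors import ConfigurationError


class TestSoftDice:
    def test_perfect_prediction_scores_one(self):
        y = uf.one_hot_encode(np.array([[0, 1], [1, 1]])[None], 2)
        assert np.allclose(uf.soft_dice(y, y).per_class, 1.0, atol=1e-6)

    def test_sixteen_position_fixture(self, sixteen_position_fixture):
        p, y = sixteen_position_fixture
        assert uf.soft_dice(p, y).per_class[0, 1] == pytest.approx(1 / 3, abs=1e-4)

    def test_disjoint_prediction_near_zero(self):
        labels = np.array([[1, 0], [0, 0]])[None]
        pred = np.array([[0, 1], [1, 1]])[None]
        score = uf.soft_dice(uf.one_hot_encode(pred, 2), uf.one_hot_encode(labels, 2))
        assert score.per_class[0, 1] < 1e-5


class TestTverskyIndex:
    def test_symmetric_weights_reduce_to_dice(self, random_batch):
        p, y = random_batch
        assert np.allclose(uf.tversky_index(p, y, 0.5, 0.5).per_class,
                           uf.soft_dice(p, y).per_class, atol=1e-12)

    def test_sixteen_position_fixture(self, sixteen_position_fixture):
        p, y = sixteen_position_fixture
        assert uf.tversky_index(p, y, 0.3, 0.7).per_class[0, 1] == pytest.approx(
            2 / 5.2, abs=1e-4)

    def test_modified_index_is_delta_parameterisation(self, sixteen_position_fixture):
        p, y = sixteen_position_fixture
        mti = uf.modified_tversky_index(p, y, 0.6)
        assert mti.per_class[0, 1] == pytest.approx(0.3125, abs=1e-4)
        assert np.allclose(mti.per_class,
                           uf.tversky_index(p, y, 0.6, 0.4).per_class, atol=1e-12)
        assert np.allclose(uf.modified_tversky_index(p, y, 0.7).per_class,
                           uf.tversky_index(p, y, 0.7, 0.3).per_class, atol=1e-12)

    def test_negative_weights_rejected(self, random_batch):
        p, y = random_batch
        with pytest.raises(ConfigurationError):
            uf.tversky_index(p, y, -0.1, 0.7)


class TestRegionLosses:
    def test_dice_loss_equals_symmetric_tversky_loss(self, rng):
        for _ in range(100):
            p, y = make_random_batch(rng)
            diff = abs(uf.dice_loss(p, y).value - uf.tversky_loss(p, y, 0.5, 0.5).value)
            assert diff < 1e-9

    def test_focal_tversky_gamma_one_is_tversky(self, rng):
        for _ in range(100):
            p, y = make_random_batch(rng)
            diff = abs(uf.focal_tversky_loss(p, y, 0.3, 0.7, 1.0).value
                       - uf.tversky_loss(p, y, 0.3, 0.7).value)
            assert diff < 1e-9

    def test_focal_tversky_transform_fixture(self):
        # (1 - TI)^(1/gamma) at TI=0.75, gamma=4/3
        from unifocal.region import region_focal_term

        got = region_focal_term(np.array(0.25), 1.0 / (4.0 / 3.0))
        assert float(got) == pytest.approx(0.25 ** 0.75, abs=1e-12)

    def test_modified_focal_tversky_gamma_zero_recovers_dice(self, rng):
        for _ in range(100):
            p, y = make_random_batch(rng)
            diff = abs(uf.modified_focal_tversky_loss(p, y, 0.5, 0.0).value
                       - uf.dice_loss(p, y).value)
            assert diff < 1e-9

    def test_modified_focal_tversky_transform_fixture(self):
        from unifocal.region import region_focal_term

        got = region_focal_term(np.array(1.0 - 0.3125), 1.0 - 0.5)
        assert float(got) == pytest.approx(0.6875 ** 0.5, abs=1e-12)

    def test_asymmetric_two_class_hand_fixture(self):
        # background 1-mTI = 0.1 unenhanced, rare (1-mTI)^(1-gamma) = 0.6875^0.5
        from unifocal.region import region_focal_term

        background = 0.1
        rare = float(region_focal_term(np.array(0.6875), 0.5))
        assert background + rare == pytest.approx(0.9292, abs=1e-4)

    def test_asymmetric_gamma_zero_is_plain_tversky_delta(self, rng):
        for _ in range(50):
            p, y = make_random_batch(rng)
            diff = abs(
                uf.modified_asymmetric_focal_tversky_loss(p, y, 0.6, 0.0).value
                - uf.tversky_loss(p, y, 0.6, 0.4).value)
            assert diff < 1e-9

    def test_rare_term_enhanced_relative_to_plain(self, sixteen_position_fixture):
        p, y = sixteen_position_fixture
        enhanced = uf.modified_asymmetric_focal_tversky_loss(p, y, 0.6, 0.5).value
        plain = uf.tversky_loss(p, y, 0.6, 0.4).value
        assert enhanced > plain  # x^(1-gamma) >= x on [0, 1]

    def test_foreground_only_class_set_mode(self, sixteen_position_fixture):
        p, y = sixteen_position_fixture
        all_classes = uf.dice_loss(p, y, classes="all")
        fg_only = uf.dice_loss(p, y, classes="foreground")
        assert fg_only.value == pytest.approx(2 / 3, abs=1e-4)
        assert all_classes.value > fg_only.value

    def test_delta_direction_depends_on_fp_fn_balance(self, sixteen_position_fixture):
        # delta multiplies the FP term: with fp > fn the loss grows with delta,
        # with fn > fp it shrinks (mirror fixture swaps prediction and truth).
        p, y = sixteen_position_fixture  # foreground fp=6 > fn=2
        assert uf.tversky_loss(p, y, 0.7, 0.3, classes="foreground").value > \
            uf.tversky_loss(p, y, 0.3, 0.7, classes="foreground").value
        # fn-dominated fixture: truth all foreground, prediction mostly background
        p_weak = np.broadcast_to([0.9, 0.1], (1, 4, 4, 2)).copy()
        y_fg = uf.one_hot_encode(np.ones((1, 4, 4), dtype=int), 2)
        assert uf.tversky_loss(p_weak, y_fg, 0.3, 0.7, classes="foreground").value > \
            uf.tversky_loss(p_weak, y_fg, 0.7, 0.3, classes="foreground").value

    def test_region_loss_bounds(self, rng):
        for _ in range(20):
            p, y = make_random_batch(rng, num_classes=3)
            value = uf.tversky_loss(p, y, 0.3, 0.7).value
            assert 0.0 <= value <= 3.0


class TestLoopOracleAgreement:
    @pytest.mark.parametrize("vector,scalar", [
        (lambda p, y: uf.dice_loss(p, y),
         lambda p, y: oracles.region_loss_item(p, y, 0.5, 0.5, 1.0)),
        (lambda p, y: uf.tversky_loss(p, y, 0.3, 0.7),
         lambda p, y: oracles.region_loss_item(p, y, 0.3, 0.7, 1.0)),
        (lambda p, y: uf.focal_tversky_loss(p, y, 0.3, 0.7, 4 / 3),
         lambda p, y: oracles.region_loss_item(p, y, 0.3, 0.7, 0.75)),
        (lambda p, y: uf.modified_focal_tversky_loss(p, y, 0.6, 0.5),
         lambda p, y: oracles.region_loss_item(p, y, 0.6, 0.4, 0.5)),
        (lambda p, y: uf.modified_asymmetric_focal_tversky_loss(p, y, 0.6, 0.5),
         lambda p, y: oracles.asymmetric_region_loss_item(p, y, 0.6, 0.5, {1})),
    ])
    def test_vectorized_equals_position_loop(self, vector, scalar):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p, y = make_random_batch(rng)
            got = vector(p, y)
            want = np.mean([scalar(p[i], y[i]) for i in range(p.shape[0])])
            assert got.value == pytest.approx(want, abs=1e-9)
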