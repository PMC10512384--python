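"""F-loss, weighted final loss, confusion metrics and HD95."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from kspc import SegmentationMask, confusion_metrics, f_loss, final_loss, hd95
from kspc.metrics import UndefinedDistanceError, _boundary_points_mm


def _mask(indicator, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(indicator=np.asarray(indicator, dtype=bool), spacing=spacing)


class TestFLoss:
    def test_perfect_prediction(self):
        y = np.ones(8)
        assert f_loss(y, y, beta=2.0) <= 1e-8

    def test_zero_overlap(self):
        y = np.zeros(20)
        y[:10] = 1
        assert f_loss(y, np.zeros(20), beta=2.0) == pytest.approx(1.0, abs=1e-8)

    def test_hand_computed_example(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        y_hat = np.array([1.0, 0.0, 1.0, 0.0])
        # 1 - 5*1 / (2 + 4*2) = 0.5
        assert f_loss(y, y_hat, beta=2.0) == pytest.approx(0.5, abs=1e-7)

    def test_beta_one_is_dice_loss(self, rng):
        for _ in range(100):
            y = rng.random(64) > 0.5
            y_hat = rng.random(64) > 0.5
            tp = float((y & y_hat).sum())
            fp = float((~y & y_hat).sum())
            fn = float((y & ~y_hat).sum())
            dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
            assert f_loss(y.astype(float), y_hat.astype(float), beta=1.0) == pytest.approx(
                1.0 - dice, abs=1e-9
            )

    def test_more_overlap_never_hurts(self):
        # at fixed prediction and target sums, increasing the overlap term
        # strictly decreases the loss
        y = np.array([1.0, 1.0, 0.0, 0.0])
        low = f_loss(y, np.array([0.0, 0.0, 0.5, 0.5]), beta=2.0)
        high = f_loss(y, np.array([0.5, 0.5, 0.0, 0.0]), beta=2.0)
        assert high < low

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            f_loss(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            f_loss(np.ones(3), np.ones(3), beta=0.0)


class TestFinalLoss:
    def test_alpha_selects_stage(self):
        assert final_loss(1.0, 0.0, alpha=0.7) == pytest.approx(0.7)
        assert final_loss(0.2, 0.8, alpha=0.0) == pytest.approx(0.8)

    def test_convex_combination(self):
        for alpha in (0.0, 0.3, 0.7, 1.0):
            assert final_loss(0.42, 0.42, alpha) == pytest.approx(0.42)
            val = final_loss(0.1, 0.9, alpha)
            assert min(0.1, 0.9) <= val <= max(0.1, 0.9)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            final_loss(0.5, 0.5, alpha=1.2)


class TestConfusionMetrics:
    def test_identical_masks(self):
        ind = np.zeros((4, 4, 4), dtype=bool)
        ind[1:3, 1:3, 1:3] = True
        rep = confusion_metrics(_mask(ind), _mask(ind))
        assert rep.dice == rep.precision == rep.recall == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        rep = confusion_metrics(_mask(a), _mask(b))
        assert rep.dice == rep.precision == rep.recall == 0.0

    def test_hand_counts(self):
        truth = np.array([1, 1, 0, 0], dtype=bool).reshape(4, 1, 1)
        pred = np.array([1, 0, 1, 0], dtype=bool).reshape(4, 1, 1)
        rep = confusion_metrics(_mask(truth), _mask(pred))
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert rep.dice == rep.precision == rep.recall == 0.5

    def test_empty_conventions(self):
        empty = _mask(np.zeros((3, 3, 3), dtype=bool))
        nonempty = np.zeros((3, 3, 3), dtype=bool)
        nonempty[1, 1, 1] = True
        rep = confusion_metrics(empty, empty)
        assert rep.dice == rep.precision == rep.recall == 1.0
        rep = confusion_metrics(empty, _mask(nonempty))
        assert rep.recall == 1.0 and rep.precision == 0.0 and rep.dice == 0.0

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics(
                _mask(np.zeros((3, 3, 3), dtype=bool)),
                _mask(np.zeros((3, 3, 3), dtype=bool), spacing=(2, 2, 2)),
            )

    def test_random_masks_dice_identity(self, rng):
        for _ in range(20):
            a = _mask(rng.random((6, 6, 6)) > 0.5)
            b = _mask(rng.random((6, 6, 6)) > 0.5)
            rep = confusion_metrics(a, b)
            assert 0.0 <= rep.dice <= 1.0
            if 2 * rep.tp + rep.fp + rep.fn:
                assert rep.dice == pytest.approx(
                    2 * rep.tp / (2 * rep.tp + rep.fp + rep.fn)
                )


def _hd95_bruteforce(a, b):
    pa = _boundary_points_mm(a)
    pb = _boundary_points_mm(b)
    d = cdist(pa, pb)
    pooled = np.sort(np.concatenate([d.min(axis=1), d.min(axis=0)]))
    return float(pooled[int(np.ceil(0.95 * pooled.size)) - 1])


class TestHD95:
    def test_identical_masks(self):
        ind = np.zeros((6, 6, 6), dtype=bool)
        ind[2:5, 2:5, 2:5] = True
        assert hd95(_mask(ind), _mask(ind)) == 0.0

    def test_two_voxels_three_mm_apart(self):
        a = np.zeros((8, 4, 4), dtype=bool)
        b = np.zeros((8, 4, 4), dtype=bool)
        a[2, 1, 1] = True
        b[5, 1, 1] = True
        assert hd95(_mask(a), _mask(b)) == pytest.approx(3.0)

    def test_spacing_in_mm(self):
        a = np.zeros((8, 4, 4), dtype=bool)
        b = np.zeros((8, 4, 4), dtype=bool)
        a[2, 1, 1] = True
        b[3, 1, 1] = True
        assert hd95(_mask(a, (2.5, 1, 1)), _mask(b, (2.5, 1, 1))) == pytest.approx(2.5)

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(10):
            a = rng.random((10, 10, 10)) > 0.7
            b = rng.random((10, 10, 10)) > 0.7
            if not (a.any() and b.any()):
                continue
            ma, mb = _mask(a), _mask(b)
            assert hd95(ma, mb) == pytest.approx(_hd95_bruteforce(ma, mb), rel=1e-12)
            assert hd95(ma, mb) == hd95(mb, ma)  # symmetry

    def test_translation_bound(self):
        ind = np.zeros((16, 8, 8), dtype=bool)
        ind[4:8, 2:6, 2:6] = True
        shifted = np.roll(ind, 2, axis=0)
        base = hd95(_mask(ind), _mask(ind))
        moved = hd95(_mask(ind), _mask(shifted))
        assert moved <= base + 2.0 + 1e-9

    def test_empty_mask_undefined(self):
        ind = np.zeros((4, 4, 4), dtype=bool)
        ind[1, 1, 1] = True
        with pytest.raises(UndefinedDistanceError):
            hd95(_mask(ind), _mask(np.zeros((4, 4, 4), dtype=bool)))
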