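"""Bounding box, coarse-derived threshold, bandwidth aggregation, refinement."""

import numpy as np
import pytest
from scipy import ndimage

from kspc import (
    Bandwidth,
    CoarseOutput,
    EmptyCoarseMaskError,
    SegmentationMask,
    aggregate_bandwidth,
    bounding_box,
    confusion_metrics,
    refine,
    threshold_from_coarse,
)
from kspc.phantom import PhantomSpec, generate_dataset


def _mask(indicator, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(indicator=indicator, spacing=spacing)


class TestBoundingBox:
    @pytest.mark.parametrize(
        "margin, expected", [(5, (5, 26)), (0, (10, 21))]
    )
    def test_cube_mask(self, margin, expected):
        ind = np.zeros((64, 64, 64), dtype=bool)
        ind[10:21, 10:21, 10:21] = True
        box = bounding_box(_mask(ind), margin)
        assert box.lower == (expected[0],) * 3
        assert box.upper == (expected[1],) * 3

    def test_corner_clipping(self):
        ind = np.zeros((8, 8, 8), dtype=bool)
        ind[0, 0, 0] = True
        box = bounding_box(_mask(ind), 3)
        assert box.lower == (0, 0, 0)
        assert box.upper == (4, 4, 4)

    def test_margin_monotone(self):
        ind = np.zeros((32, 32, 32), dtype=bool)
        ind[10:14, 12:18, 9:11] = True
        boxes = [bounding_box(_mask(ind), m) for m in range(0, 6)]
        for small, big in zip(boxes, boxes[1:]):
            assert all(b <= s for s, b in zip(small.lower, big.lower))
            assert all(b >= s for s, b in zip(small.upper, big.upper))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyCoarseMaskError):
            bounding_box(_mask(np.zeros((4, 4, 4), dtype=bool)), 0)


class TestThresholdFromCoarse:
    def _density_with_values(self, vals):
        from kspc.kde import DensityManifold

        arr = np.zeros((10, 1, 1))
        arr[:, 0, 0] = vals
        dens = DensityManifold(
            density=arr, spacing=(1, 1, 1), origin=(0, 0, 0),
            total_suv=1.0, bandwidth=Bandwidth(1, 1, 1),
        )
        return dens

    def test_order_statistics(self):
        dens = self._density_with_values(np.arange(1, 11) / 10.0)
        mask = _mask(np.ones((10, 1, 1), dtype=bool))
        assert threshold_from_coarse(dens, mask, 0.10) == pytest.approx(0.1)
        assert threshold_from_coarse(dens, mask, 0.0) == pytest.approx(0.1)  # minimum
        assert threshold_from_coarse(dens, mask, 0.25) == pytest.approx(0.3)

    def test_single_voxel_mask(self):
        dens = self._density_with_values(np.arange(1, 11) / 10.0)
        ind = np.zeros((10, 1, 1), dtype=bool)
        ind[6, 0, 0] = True
        for frac in (0.0, 0.1, 0.9):
            assert threshold_from_coarse(dens, _mask(ind), frac) == pytest.approx(0.7)

    def test_empty_mask(self):
        dens = self._density_with_values(np.arange(1, 11) / 10.0)
        with pytest.raises(EmptyCoarseMaskError):
            threshold_from_coarse(dens, _mask(np.zeros((10, 1, 1), dtype=bool)), 0.1)


class TestAggregateBandwidth:
    def test_constant_channels(self):
        vol = np.ones((3, 3, 3, 3)) * np.array([1.5, 2.0, 2.5])
        h = aggregate_bandwidth(vol)
        assert (h.hx, h.hy, h.hz) == (1.5, 2.0, 2.5)

    def test_two_voxel_mean(self):
        vol = np.ones((2, 1, 1, 3))
        vol[0, 0, 0, 0], vol[1, 0, 0, 0] = 1.0, 3.0
        assert aggregate_bandwidth(vol).hx == pytest.approx(2.0)

    def test_random_mean_oracle(self, rng):
        vol = rng.random((4, 4, 4, 3)) + 0.1
        h = aggregate_bandwidth(vol).as_array()
        expected = [vol[..., d].sum() / 64 for d in range(3)]
        np.testing.assert_allclose(h, expected, rtol=1e-12)

    def test_rejects_nonpositive_mean(self):
        vol = np.zeros((2, 2, 2, 3))
        with pytest.raises(ValueError):
            aggregate_bandwidth(vol)


class TestRefine:
    @pytest.fixture(scope="class")
    def phantom_pair(self):
        return generate_dataset(1, PhantomSpec(), seed=7)[0]

    def test_geometry_and_subset(self, phantom_pair):
        image, truth = phantom_pair
        coarse = CoarseOutput(coarse_mask=truth, bandwidth=Bandwidth(2, 2, 2))
        mask, contour_set = refine(image, coarse, margin_voxels=8)
        assert mask.dims == image.dims
        box = bounding_box(truth, 8)
        outside = np.ones(image.dims, dtype=bool)
        outside[box.slices] = False
        assert not mask.indicator[outside].any()
        assert len(contour_set) == 5

    def test_truth_as_coarse_recovers_truth(self, phantom_pair):
        """A perfect coarse mask refines to Dice >= 0.90 against the truth."""
        image, truth = phantom_pair
        coarse = CoarseOutput(coarse_mask=truth, bandwidth=Bandwidth(2, 2, 2))
        mask, _ = refine(image, coarse)
        assert confusion_metrics(truth, mask).dice >= 0.90

    def test_refinement_preserves_good_coarse(self, phantom_pair):
        """Refining a perfect coarse mask keeps Dice near the trimming bound.

        The robust quantile discards the lowest-density 10% of the coarse
        region, so a perfect coarse mask refines to ~90% of its volume and
        the best achievable Dice is 2(1-q)/(2-q) ~ 0.947 at q = 0.10.
        """
        image, truth = phantom_pair
        for h in (1.0, 2.0, 3.0):  # bandwidths below the blob sigma
            coarse = CoarseOutput(coarse_mask=truth, bandwidth=Bandwidth(h, h, h))
            mask, _ = refine(image, coarse)
            assert confusion_metrics(truth, mask).dice >= 0.90

    def test_empty_coarse_mask(self, phantom_pair):
        image, _ = phantom_pair
        empty = _mask(np.zeros(image.dims, dtype=bool))
        with pytest.raises(EmptyCoarseMaskError):
            refine(image, CoarseOutput(coarse_mask=empty, bandwidth=Bandwidth(2, 2, 2)))
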