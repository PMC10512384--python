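"""Level sets, weighted quantile thresholds and probability contours."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from kspc import (
    Bandwidth,
    KsPC,
    VolumetricImage,
    estimate_density,
    extract_level_set,
    mask_to_surface,
    probability_contours,
    probability_threshold,
    weighted_quantile,
)
from kspc.contours import EmptySurfaceError
from kspc.phantom import Blob, PhantomSpec, generate_phantom

SIX_CONN = ndimage.generate_binary_structure(3, 1)


class TestLevelSet:
    def test_threshold_extremes(self, blob_results):
        dens = blob_results.density
        assert extract_level_set(dens, -1.0).indicator.all()
        assert extract_level_set(dens, float(dens.density.max())).is_empty()

    def test_half_peak_is_single_component_containing_peak(self, blob_results):
        dens = blob_results.density
        mask = extract_level_set(dens, float(dens.density.max()) / 2.0)
        labels, n = ndimage.label(mask.indicator, structure=SIX_CONN)
        assert n == 1
        peak = np.unravel_index(np.argmax(dens.density), dens.dims)
        assert mask.indicator[peak]

    def test_non_finite_threshold_rejected(self, blob_results):
        with pytest.raises(ValueError):
            extract_level_set(blob_results.density, np.nan)


class TestWeightedQuantile:
    @given(
        st.lists(st.integers(0, 5), min_size=8, max_size=216).filter(lambda v: sum(v) > 0),
        st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.9, 1.0]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_repetition_expansion(self, weights, omega):
        # integer weights: the weighted quantile equals the plain nearest-rank
        # quantile of the list with each value repeated weight times
        rng = np.random.default_rng(len(weights))
        values = rng.random(len(weights))
        w = np.array(weights, dtype=float)
        keep = w > 0
        expanded = np.sort(np.repeat(values[keep], w[keep].astype(int)))
        rank = max(int(np.ceil(omega * expanded.size)) - 1, 0)
        assert weighted_quantile(values[keep], w[keep], omega) == expanded[rank]

    def test_omega_bounds(self, blob_results, blob_phantom):
        image, _ = blob_phantom
        dens = blob_results.density
        pos = image.values > 0
        assert probability_threshold(dens, image, 0.0) == dens.density[pos].min()
        assert probability_threshold(dens, image, 1.0) == dens.density[pos].max()
        with pytest.raises(ValueError):
            probability_threshold(dens, image, 1.5)


class TestProbabilityContours:
    def test_mass_calibration(self, blob_results):
        """Contours at omega enclose ~(1 - omega) of the probability mass."""
        cs = blob_results.probability_contours((0.1, 0.3, 0.5, 0.7, 0.9))
        for om, mass in zip(cs.levels, cs.enclosed_mass):
            assert mass == pytest.approx(1.0 - om, abs=0.02)

    def test_nesting_and_monotonicity_on_random_phantoms(self):
        for seed in range(5):
            spec = PhantomSpec(dims=(48, 48, 48), seed=seed,
                               blobs=(Blob((23.5, 23.5, 23.5), (5.0, 6.0, 4.0), 9.0),))
            image, _ = generate_phantom(spec)
            cs = KsPC(image, (2, 2, 2)).fit().probability_contours()
            assert all(np.diff(cs.thresholds) >= 0)
            for outer, inner in zip(cs.masks, cs.masks[1:]):
                assert (inner.indicator <= outer.indicator).all()
                assert inner.count() < outer.count()  # strictly nested
            assert all(np.diff(cs.enclosed_mass) <= 0)

    def test_scale_invariance(self, blob_phantom):
        image, _ = blob_phantom
        h = Bandwidth(2, 2, 2)
        cs1 = probability_contours(estimate_density(image, h), image)
        scaled = VolumetricImage(values=3.7 * image.values, spacing=image.spacing)
        cs2 = probability_contours(estimate_density(scaled, h), scaled)
        np.testing.assert_allclose(cs1.thresholds, cs2.thresholds, rtol=1e-9)
        dens = estimate_density(image, h)
        for m1, m2, lam in zip(cs1.masks, cs2.masks, cs1.thresholds):
            diff = m1.indicator != m2.indicator
            # only voxels whose density ties the threshold to rounding may flip
            assert np.all(np.abs(dens.density[diff] - lam) <= 1e-9 * lam)

    def test_invalid_levels(self, blob_results, blob_phantom):
        image, _ = blob_phantom
        with pytest.raises(ValueError):
            probability_contours(blob_results.density, image, levels=(0.5, 0.5))
        with pytest.raises(ValueError):
            probability_contours(blob_results.density, image, levels=())
        with pytest.raises(ValueError):
            probability_contours(blob_results.density, image, levels=(0.0, 0.5))


class TestSurface:
    def test_sphere_topology(self, blob_results):
        dens = blob_results.density
        surf = mask_to_surface(dens, float(dens.density.max()) / 2.0)
        assert len(surf.faces) > 0
        assert surf.euler_characteristic() == 2  # topological sphere

    def test_out_of_range_isovalue(self, blob_results):
        with pytest.raises(EmptySurfaceError):
            mask_to_surface(blob_results.density, float(blob_results.density.density.max()))

    def test_two_blobs_two_components(self):
        spec = PhantomSpec(
            dims=(64, 64, 64),
            blobs=(
                Blob((15.0, 31.5, 31.5), (4.0, 4.0, 4.0), 8.0),
                Blob((48.0, 31.5, 31.5), (4.0, 4.0, 4.0), 8.0),
            ),
            background_level=0.0,
            noise_scale=0.0,
        )
        image, _ = generate_phantom(spec)
        dens = estimate_density(image, Bandwidth(2, 2, 2))
        mask = extract_level_set(dens, float(dens.density.max()) / 2.0)
        _, n = ndimage.label(mask.indicator, structure=SIX_CONN)
        assert n == 2
        surf = mask_to_surface(dens, float(dens.density.max()) / 2.0)
        import trimesh

        mesh = trimesh.Trimesh(vertices=surf.vertices, faces=surf.faces, process=False)
        assert len(mesh.split(only_watertight=False)) == 2
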