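"""Model/Results interface over the kernel-smoothing probability contours.

`KsPC` is the nonparametric model — an SUV-weighted trivariate Gaussian
kernel density over a volumetric image; `fit()` estimates the density and
returns a `KsPCResults` carrying the manifold, from which level sets,
probability thresholds, contour sets and surfaces are derived, with a
printable `summary()`. `CoarseToFineKsPC` wraps the two-phase pipeline where
a coarse mask supplies the bounding box, bandwidth and quantile threshold.
"""

from __future__ import annotations

import numpy as np

from . import contours as _contours
from .coarse_to_fine import CoarseOutput, refine
from .contours import DEFAULT_LEVELS, ProbabilityContourSet, SurfaceMesh
from .grid import Bandwidth, SegmentationMask, VolumetricImage
from .kde import DensityManifold, estimate_density


class KsPC:
    """SUV-weighted kernel density model of a volumetric PET image.

    Parameters
    ----------
    image : VolumetricImage
        Non-negative SUV volume with at least one positive voxel.
    bandwidth : Bandwidth or 3 floats
        Per-axis Gaussian smoothing scale in mm.
    truncation_radius : float
        Kernel support half-width in bandwidth units for the separable path.
    """

    def __init__(self, image: VolumetricImage, bandwidth, truncation_radius: float = 6.0):
        self.image = image
        self.bandwidth = (
            bandwidth if isinstance(bandwidth, Bandwidth) else Bandwidth(*bandwidth)
        )
        self.truncation_radius = truncation_radius

    @classmethod
    def from_array(cls, values, bandwidth, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                   **kwargs):
        """Build the model directly from a 3D array of SUVs."""
        return cls(VolumetricImage(values=values, spacing=spacing, origin=origin),
                   bandwidth, **kwargs)

    def fit(self, method: str = "separable") -> "KsPCResults":
        """Estimate the density manifold and return the results object."""
        density = estimate_density(
            self.image, self.bandwidth, method=method,
            truncation_radius=self.truncation_radius,
        )
        return KsPCResults(self, density)


class KsPCResults:
    """Fitted kernel-density manifold with its derived segmentations."""

    def __init__(self, model: KsPC, density: DensityManifold):
        self.model = model
        self.density = density

    def level_set(self, lam: float) -> SegmentationMask:
        """Hard segmentation {f_hat > lam}."""
        return _contours.extract_level_set(self.density, lam)

    def probability_threshold(self, omega: float) -> float:
        """lambda_omega: the SUV-weighted omega-quantile of density values."""
        return _contours.probability_threshold(self.density, self.model.image, omega)

    def probability_contours(self, levels=DEFAULT_LEVELS) -> ProbabilityContourSet:
        """Nested probability volume contours at the given omega levels."""
        return _contours.probability_contours(self.density, self.model.image, levels)

    def surface(self, lam: float) -> SurfaceMesh:
        """Marching-cubes isosurface of the density at ``lam``, in mm."""
        return _contours.mask_to_surface(self.density, lam)

    def summary(self, levels=DEFAULT_LEVELS) -> str:
        """Tabular overview: bandwidth, mass balance, and per-level contours."""
        cs = self.probability_contours(levels)
        h = self.model.bandwidth
        lines = [
            "KsPC density manifold",
            "=" * 64,
            f"grid dims          : {self.density.dims}",
            f"voxel spacing (mm) : {tuple(round(s, 4) for s in self.density.spacing)}",
            f"bandwidth h (mm)   : ({h.hx:.4g}, {h.hy:.4g}, {h.hz:.4g})",
            f"total SUV          : {self.density.total_suv:.6g}",
            f"discrete integral  : {self.density.discrete_integral():.6f}",
            "-" * 64,
            f"{'omega':>7} {'lambda_omega':>14} {'encl. mass':>11} "
            f"{'dens. mass':>11} {'voxels':>8}",
        ]
        for om, lam, em, dm, nvox in cs.table():
            lines.append(f"{om:>7.2f} {lam:>14.6e} {em:>11.4f} {dm:>11.4f} {nvox:>8d}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_slice(self, axis: int = 2, index: int | None = None, levels=DEFAULT_LEVELS,
                   ax=None):
        """Overlay contour outlines on a 2D slice of the raw image."""
        import matplotlib.pyplot as plt

        if index is None:
            index = self.density.dims[axis] // 2
        take = [slice(None)] * 3
        take[axis] = index
        take = tuple(take)
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.model.image.values[take].T, origin="lower", cmap="magma")
        cs = self.probability_contours(levels)
        for lam in cs.thresholds:
            ax.contour(self.density.density[take].T, levels=[lam], colors="cyan",
                       linewidths=0.8)
        ax.set_title(f"probability contours (axis {axis}, slice {index})")
        return ax


class CoarseToFineKsPC:
    """Two-phase pipeline: a coarse mask drives a cropped KsPC refinement."""

    def __init__(self, image: VolumetricImage, coarse: CoarseOutput,
                 margin_voxels: int = 8, levels=DEFAULT_LEVELS,
                 truncation_radius: float = 6.0):
        self.image = image
        self.coarse = coarse
        self.margin_voxels = margin_voxels
        self.levels = tuple(levels)
        self.truncation_radius = truncation_radius

    def fit(self) -> "CoarseToFineResults":
        mask, contour_set = refine(
            self.image, self.coarse, margin_voxels=self.margin_voxels,
            levels=self.levels, truncation_radius=self.truncation_radius,
        )
        return CoarseToFineResults(self, mask, contour_set)


class CoarseToFineResults:
    def __init__(self, model: CoarseToFineKsPC, mask: SegmentationMask,
                 contour_set: ProbabilityContourSet):
        self.model = model
        self.mask = mask
        self.contour_set = contour_set

    def summary(self) -> str:
        h = self.model.coarse.bandwidth
        lines = [
            "Coarse-to-fine KsPC segmentation",
            "=" * 64,
            f"grid dims          : {self.mask.dims}",
            f"bandwidth h (mm)   : ({h.hx:.4g}, {h.hy:.4g}, {h.hz:.4g})",
            f"quantile threshold : {self.model.coarse.quantile_threshold:.3f}",
            f"coarse voxels      : {self.model.coarse.coarse_mask.count()}",
            f"final voxels       : {self.mask.count()}",
            "-" * 64,
            f"{'omega':>7} {'lambda_omega':>14} {'encl. mass':>11} {'voxels':>8}",
        ]
        for om, lam, em, _, nvox in self.contour_set.table():
            lines.append(f"{om:>7.2f} {lam:>14.6e} {em:>11.4f} {nvox:>8d}")
        lines.append("=" * 64)
        return "\n".join(lines)
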