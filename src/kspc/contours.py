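"""Level-set segmentation and probability volume contours.

A threshold lambda on the kernel-smoothed density defines the segmentation
region {p : f_hat(p) > lambda}. Probability volume contours pick lambda so
that the enclosed region carries a nominal share of the probability mass:
lambda_omega is the omega-quantile of the density values observed at the data
points. Because a voxel with SUV s_i stands for s_i coincident observations,
that quantile is SUV-weighted. The region above lambda_omega then contains a
fraction 1 - omega of the data probability mass — these are highest-density
regions, and they are invariant to rescaling all SUVs by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .grid import DegenerateInputError, SegmentationMask, VolumetricImage
from .kde import DensityManifold


def extract_level_set(density: DensityManifold, lam: float) -> SegmentationMask:
    """Segmentation mask {voxel : f_hat(voxel) > lam} (strict inequality).

    The region may be connected or disconnected; no morphological cleanup is
    applied.
    """
    if not np.isfinite(lam):
        raise ValueError("level-set threshold must be finite")
    return SegmentationMask(
        indicator=density.density > lam,
        spacing=density.spacing,
        origin=density.origin,
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, omega: float) -> float:
    """Weighted inverse empirical CDF (lower nearest-rank, no interpolation).

    Returns the smallest value v with cumulative weight fraction >= omega.
    Equals the plain nearest-rank quantile of the list where each value is
    repeated ``weight`` times, for integer weights.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"quantile level must be in [0, 1], got {omega}")
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty value list for weighted quantile")
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("weights sum to zero")
    order = np.argsort(values, kind="stable")
    cdf = np.cumsum(weights[order]) / total
    idx = int(np.searchsorted(cdf, omega, side="left"))
    idx = min(idx, values.size - 1)
    return float(values[order][idx])


def probability_threshold(
    density: DensityManifold, image: VolumetricImage, omega: float
) -> float:
    """Threshold lambda_omega = SUV-weighted omega-quantile of density values.

    Only voxels with positive SUV contribute (zero-weight voxels are not data
    points). omega = 0 gives the minimum density over uptake voxels, omega = 1
    the maximum.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    if not density.same_geometry(image):
        raise ValueError("density and image geometries do not match")
    w = image.values.ravel()
    mask = w > 0
    if not mask.any():
        raise DegenerateInputError("all-zero SUV volume has no data points")
    return weighted_quantile(density.density.ravel()[mask], w[mask], omega)


DEFAULT_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ProbabilityContourSet:
    """Nested level-set masks at thresholds lambda_omega for ordered levels.

    ``enclosed_mass[i]`` is the probability mass of the data (SUV fraction)
    inside mask i, approximately 1 - levels[i] on well-resolved densities;
    ``density_mass[i]`` is the discrete integral of the density inside mask i,
    a secondary diagnostic that differs from enclosed_mass by the kernel
    smoothing bias.
    """

    levels: tuple
    thresholds: tuple
    masks: list
    enclosed_mass: tuple
    density_mass: tuple

    def __post_init__(self):
        t = np.asarray(self.thresholds)
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be non-decreasing in omega")
        m = np.asarray(self.enclosed_mass)
        if np.any(np.diff(m) > 1e-12):
            raise ValueError("enclosed mass must be non-increasing in omega")

    def __len__(self) -> int:
        return len(self.levels)

    def label_volume(self) -> np.ndarray:
        """Integer label per voxel: number of contours containing it (0 = outside all)."""
        out = np.zeros(self.masks[0].dims, dtype=np.int16)
        for m in self.masks:
            out += m.indicator.astype(np.int16)
        return out

    def table(self):
        """Rows of (omega, lambda_omega, enclosed_mass, density_mass, voxels)."""
        return [
            (om, lam, em, dm, m.count())
            for om, lam, em, dm, m in zip(
                self.levels, self.thresholds, self.enclosed_mass, self.density_mass, self.masks
            )
        ]


def probability_contours(
    density: DensityManifold,
    image: VolumetricImage,
    levels=DEFAULT_LEVELS,
) -> ProbabilityContourSet:
    """Compute the probability volume contour set at the given omega levels.

    The default levels (0.1, 0.3, 0.5, 0.7, 0.9) yield contours enclosing
    roughly 90%, 70%, 50%, 30% and 10% of the probability mass (outer to
    inner) — the nested sub-volumes used by dose-painting-by-contours plans.
    """
    levels = tuple(levels)
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate contour levels")
    if any(not (0.0 < om < 1.0) for om in levels):
        raise ValueError("each level must lie strictly inside (0, 1)")
    levels = tuple(sorted(levels))
    suv_total = image.values.sum()
    thresholds, masks, data_mass, dens_mass = [], [], [], []
    for om in levels:
        lam = probability_threshold(density, image, om)
        mask = extract_level_set(density, lam)
        thresholds.append(lam)
        masks.append(mask)
        data_mass.append(float(image.values[mask.indicator].sum() / suv_total))
        dens_mass.append(float(density.density[mask.indicator].sum() * density.voxel_volume))
    return ProbabilityContourSet(
        levels=levels,
        thresholds=tuple(thresholds),
        masks=masks,
        enclosed_mass=tuple(data_mass),
        density_mass=tuple(dens_mass),
    )


@dataclass
class SurfaceMesh:
    """Triangulated isosurface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a non-existent vertex")

    def euler_characteristic(self) -> int:
        edges = set()
        for a, b, c in self.faces:
            for e in ((a, b), (b, c), (a, c)):
                edges.add(tuple(sorted(e)))
        return len(self.vertices) - len(edges) + len(self.faces)


class EmptySurfaceError(ValueError):
    """Raised when the requested isovalue produces no surface."""


def mask_to_surface(density: DensityManifold, lam: float) -> SurfaceMesh:
    """Marching-cubes isosurface of the density at value ``lam``, in mm."""
    dmin, dmax = float(density.density.min()), float(density.density.max())
    if not (dmin < lam < dmax):
        raise EmptySurfaceError(
            f"isovalue {lam} outside the open density range ({dmin}, {dmax})"
        )
    verts, faces, _, _ = measure.marching_cubes(
        density.density, level=lam, spacing=density.spacing
    )
    verts = verts + np.asarray(density.origin)[None, :]
    return SurfaceMesh(vertices=verts, faces=faces)
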