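"""Two-phase coarse-to-fine segmentation.

A coarse segmenter (typically the CNN backbone, but any upstream mask works)
supplies three things: where the tumour is (a bounding box around the coarse
mask), how much to smooth (a per-voxel bandwidth feature volume averaged into
a single bandwidth vector), and where to cut (a robustified minimum — the
lower decile — of density values inside the coarse region, which shields the
threshold from outlier voxels in the coarse prediction). The fine phase runs
the kernel-density segmentation inside the cropped box only and re-embeds the
result into the full volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import (
    DEFAULT_LEVELS,
    ProbabilityContourSet,
    extract_level_set,
    probability_contours,
)
from .grid import (
    Bandwidth,
    BoundingBox,
    EmptyCoarseMaskError,
    SegmentationMask,
    VolumetricImage,
)
from .kde import DensityManifold, estimate_density


@dataclass
class CoarseOutput:
    """Everything the fine phase needs from the coarse phase."""

    coarse_mask: SegmentationMask
    bandwidth: Bandwidth
    bandwidth_volume: np.ndarray | None = None  # (nx, ny, nz, 3), positive
    quantile_threshold: float = 0.10

    def __post_init__(self):
        if not (0.0 <= self.quantile_threshold <= 1.0):
            raise ValueError("quantile_threshold must be in [0, 1]")


def bounding_box(mask: SegmentationMask, margin_voxels: int = 0) -> BoundingBox:
    """Tightest box containing the mask, dilated by a margin and clipped.

    Disconnected masks yield a single box covering all components.
    """
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be non-negative")
    if mask.is_empty():
        raise EmptyCoarseMaskError("cannot derive a bounding box from an empty mask")
    pos = np.argwhere(mask.indicator)
    lower = np.maximum(pos.min(axis=0) - margin_voxels, 0)
    upper = np.minimum(pos.max(axis=0) + 1 + margin_voxels, mask.dims)
    return BoundingBox(lower=tuple(int(v) for v in lower), upper=tuple(int(v) for v in upper))


def threshold_from_coarse(
    density: DensityManifold,
    coarse_mask: SegmentationMask,
    robust_fraction: float = 0.10,
) -> float:
    """Robustified minimum density inside the coarse region.

    Returns the ``robust_fraction`` quantile (lower nearest-rank, unweighted)
    of density values at voxels inside the coarse mask. fraction 0 is the
    literal minimum; the default 0.10 discards the influence of outlier
    voxels in the coarse prediction.
    """
    if not (0.0 <= robust_fraction <= 1.0):
        raise ValueError("robust_fraction must be in [0, 1]")
    if coarse_mask.is_empty():
        raise EmptyCoarseMaskError("coarse mask is empty")
    if not density.same_geometry(coarse_mask):
        raise ValueError("density and coarse mask geometries do not match")
    vals = np.sort(density.density[coarse_mask.indicator])
    rank = int(np.ceil(robust_fraction * vals.size)) - 1
    return float(vals[max(rank, 0)])


def aggregate_bandwidth(bandwidth_volume: np.ndarray) -> Bandwidth:
    """Average a (nx, ny, nz, 3) bandwidth feature volume into one vector h.

    Component d of h is the arithmetic mean of channel d over all voxels.
    """
    vol = np.asarray(bandwidth_volume, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] != 3:
        raise ValueError("bandwidth volume must have shape (nx, ny, nz, 3)")
    if not np.all(np.isfinite(vol)):
        raise ValueError("bandwidth volume must be finite")
    means = vol.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError(f"aggregated bandwidth must be positive, got {means}")
    return Bandwidth(*means)


def refine(
    image: VolumetricImage,
    coarse: CoarseOutput,
    margin_voxels: int = 8,
    levels=DEFAULT_LEVELS,
    truncation_radius: float = 6.0,
) -> tuple[SegmentationMask, ProbabilityContourSet]:
    """Fine-phase segmentation inside the coarse bounding box.

    Crops the image to the coarse box (plus margin), estimates the density on
    the crop with the coarse bandwidth, thresholds at the robustified minimum
    from :func:`threshold_from_coarse`, and re-embeds the mask into the full
    volume (everything outside the box is background). The contour set is
    computed on the cropped density.
    """
    if coarse.coarse_mask.is_empty():
        raise EmptyCoarseMaskError("coarse mask is empty")
    if coarse.coarse_mask.dims != image.dims:
        raise ValueError("coarse mask geometry does not match the image")
    box = bounding_box(coarse.coarse_mask, margin_voxels)
    if any(n < 2 for n in box.shape):
        raise ValueError(f"degenerate bounding box {box.shape}: need >= 2 voxels per axis")
    crop_origin = tuple(
        image.origin[d] + box.lower[d] * image.spacing[d] for d in range(3)
    )
    crop = VolumetricImage(
        values=image.values[box.slices], spacing=image.spacing, origin=crop_origin
    )
    density = estimate_density(
        crop, coarse.bandwidth, method="separable", truncation_radius=truncation_radius
    )
    crop_mask = SegmentationMask(
        indicator=coarse.coarse_mask.indicator[box.slices],
        spacing=image.spacing,
        origin=crop_origin,
    )
    lam = threshold_from_coarse(density, crop_mask, coarse.quantile_threshold)
    fine_crop = extract_level_set(density, lam)
    full = np.zeros(image.dims, dtype=bool)
    full[box.slices] = fine_crop.indicator
    final_mask = SegmentationMask(indicator=full, spacing=image.spacing, origin=image.origin)
    contour_set = probability_contours(density, crop, levels=levels)
    return final_mask, contour_set
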