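"""Voxel-grid containers shared across the toolkit.

All volumes live on axis-aligned regular grids. Indices are 0-based; the
physical position of voxel (i, j, k) is ``origin + index * spacing`` (voxel
centers, in mm). Bandwidths are expressed in mm so that smoothing scales stay
physically meaningful on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but makes the operation undefined."""


class EmptyCoarseMaskError(DegenerateInputError):
    """Raised when a coarse segmentation contains no positive voxels."""


def _as_triple(x, name: str) -> tuple:
    t = tuple(x)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 components, got {len(t)}")
    return t


@dataclass(frozen=True)
class Bandwidth:
    """Per-axis Gaussian smoothing scale h = (hx, hy, hz), in mm."""

    hx: float
    hy: float
    hz: float

    def __post_init__(self):
        for v in (self.hx, self.hy, self.hz):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"bandwidth components must be finite and > 0, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.hx, self.hy, self.hz], dtype=float)


@dataclass
class VolumetricImage:
    """A 3D grid of non-negative SUVs with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative finite voxel intensities (SUVs).
    spacing : 3 floats, mm per voxel along each axis, strictly positive.
    origin : 3 floats, mm position of voxel (0, 0, 0); default zeros.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must all be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any((not np.isfinite(s)) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coordinates(self):
        """Physical mm coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[d] + np.arange(self.dims[d]) * self.spacing[d] for d in range(3)
        )

    def same_geometry(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SegmentationMask:
    """Binary voxel mask sharing the geometry of a :class:`VolumetricImage`."""

    indicator: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator).astype(bool)
        if self.indicator.ndim != 3:
            raise ValueError("indicator must be 3D")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any((not np.isfinite(s)) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def dims(self) -> tuple:
        return self.indicator.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def count(self) -> int:
        return int(self.indicator.sum())

    def is_empty(self) -> bool:
        return not self.indicator.any()

    def same_geometry(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel-index box: inclusive lower, exclusive upper, 0-based."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        object.__setattr__(self, "lower", _as_triple(self.lower, "lower"))
        object.__setattr__(self, "upper", _as_triple(self.upper, "upper"))
        for lo, hi in zip(self.lower, self.upper):
            if not (0 <= lo < hi):
                raise ValueError(f"require 0 <= lower < upper per axis, got {self}")

    @property
    def slices(self) -> tuple:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    @property
    def shape(self) -> tuple:
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))
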