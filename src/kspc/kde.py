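"""SUV-weighted trivariate Gaussian kernel density estimation on voxel grids.

The voxel intensities (SUVs) are treated as frequencies: a voxel at position
p_i with intensity s_i behaves like s_i coincident observations at p_i. The
kernel density estimate over the grid is then

    f_hat(p; h) = (hx hy hz)^-1 (sum_i s_i)^-1
                  * sum_i K((x-x_i)/hx) K((y-y_i)/hy) K((z-z_i)/hz) s_i

with K the standard Gaussian kernel. On a regular grid this weighted sum is
exactly a separable Gaussian correlation of the SUV volume, which is how the
fast path computes it; a literal per-point accumulation is kept as the slow
reference path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .grid import Bandwidth, DegenerateInputError, VolumetricImage

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gaussian_kernel(u):
    """Standard Gaussian kernel K(u) = (2*pi)^(-1/2) exp(-u^2 / 2).

    Accepts scalars or arrays; symmetric in ``u`` and strictly positive.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("kernel argument must be finite")
    out = _INV_SQRT_2PI * np.exp(-0.5 * u * u)
    return float(out) if out.ndim == 0 else out


def total_mass(image: VolumetricImage) -> float:
    """Sum of all SUVs — the normalizer of the weighted KDE."""
    return float(image.values.sum())


@dataclass
class DensityManifold:
    """The kernel-smoothed density evaluated on the source grid.

    ``density`` integrates (discretely) to at most 1; mass leaks across the
    volume faces when the uptake support is close to the boundary because
    kernels are not renormalized there.
    """

    density: np.ndarray
    spacing: tuple
    origin: tuple
    total_suv: float
    bandwidth: Bandwidth

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be 3D")
        if np.any(self.density < 0):
            raise ValueError("density values must be non-negative")
        if self.total_suv <= 0:
            raise ValueError("total_suv must be > 0")

    @property
    def dims(self) -> tuple:
        return self.density.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def discrete_integral(self) -> float:
        """Riemann sum of the density over the grid (close to 1 away from faces)."""
        return float(self.density.sum() * self.voxel_volume)

    def same_geometry(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def kernel_taps(spacing: float, h: float, truncation_radius: float) -> np.ndarray:
    """Discrete kernel taps K(k*spacing/h) for |k*spacing| <= truncation_radius*h."""
    radius = int(np.ceil(truncation_radius * h / spacing))
    offsets = np.arange(-radius, radius + 1)
    return _INV_SQRT_2PI * np.exp(-0.5 * (offsets * spacing / h) ** 2)


def _estimate_separable(values, spacing, bandwidth, truncation_radius):
    out = values.astype(float, copy=True)
    for axis in range(3):
        taps = kernel_taps(spacing[axis], bandwidth.as_array()[axis], truncation_radius)
        out = correlate1d(out, taps, axis=axis, mode="constant", cval=0.0)
    return out


def _estimate_direct(values, axes_mm, bandwidth):
    # Literal accumulation over data voxels; oracle path, O(N^2).
    h = bandwidth.as_array()
    X, Y, Z = np.meshgrid(*axes_mm, indexing="ij")
    out = np.zeros_like(values, dtype=float)
    idx = np.argwhere(values > 0)
    for i, j, k in idx:
        s = values[i, j, k]
        kx = gaussian_kernel((X - axes_mm[0][i]) / h[0])
        ky = gaussian_kernel((Y - axes_mm[1][j]) / h[1])
        kz = gaussian_kernel((Z - axes_mm[2][k]) / h[2])
        out += s * kx * ky * kz
    return out


def estimate_density(
    image: VolumetricImage,
    bandwidth: Bandwidth,
    method: str = "separable",
    truncation_radius: float = 6.0,
) -> DensityManifold:
    """Estimate the SUV-weighted Gaussian kernel density over the voxel grid.

    Parameters
    ----------
    image : VolumetricImage
        Source volume; must contain at least one strictly positive SUV.
    bandwidth : Bandwidth
        Per-axis smoothing scale in mm.
    method : {"separable", "direct"}
        ``separable`` computes the weighted sum as three axis-wise Gaussian
        correlations truncated at ``truncation_radius`` standard deviations;
        ``direct`` accumulates the literal per-point sum (slow; reference).
    truncation_radius : float
        Kernel support half-width in units of the bandwidth (separable path).

    Returns
    -------
    DensityManifold
    """
    if not isinstance(bandwidth, Bandwidth):
        bandwidth = Bandwidth(*bandwidth)
    if truncation_radius <= 0:
        raise ValueError("truncation_radius must be > 0")
    tot = total_mass(image)
    if tot <= 0:
        raise DegenerateInputError(
            "all-zero SUV volume: the weighted density is undefined (sum of SUVs is 0)"
        )
    if any(h < s for h, s in zip(bandwidth.as_array(), image.spacing)):
        warnings.warn(
            "bandwidth smaller than voxel spacing: the density degenerates "
            "towards the scaled raw image",
            stacklevel=2,
        )
    if method == "separable":
        raw = _estimate_separable(image.values, image.spacing, bandwidth, truncation_radius)
    elif method == "direct":
        raw = _estimate_direct(image.values, image.axis_coordinates(), bandwidth)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'separable' or 'direct'")
    hx, hy, hz = bandwidth.as_array()
    density = raw / (hx * hy * hz * tot)
    np.clip(density, 0.0, None, out=density)
    return DensityManifold(
        density=density,
        spacing=image.spacing,
        origin=image.origin,
        total_suv=tot,
        bandwidth=bandwidth,
    )
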