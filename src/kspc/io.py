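"""NIfTI and mesh I/O plus run manifests.

NIfTI is the single volume dialect. Only axis-aligned affines are supported:
spacing is taken from the affine diagonal, origin from its translation
column. Masks must be binary after rounding; negative SUVs are rejected
unless clamping is requested explicitly.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np

from .contours import ProbabilityContourSet, SurfaceMesh
from .grid import SegmentationMask, VolumetricImage
from .kde import DensityManifold


class ObliqueVolumeError(ValueError):
    """Raised for NIfTI volumes whose affine is not axis-aligned."""


class InvalidMaskError(ValueError):
    """Raised when a mask file is not binary."""


def _geometry_from_affine(affine: np.ndarray):
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ObliqueVolumeError(
            "only axis-aligned NIfTI volumes are supported (oblique affine found)"
        )
    spacing = tuple(float(abs(v)) for v in np.diag(rot))
    origin = tuple(float(v) for v in affine[:3, 3])
    return spacing, origin


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path, clamp_negative: bool = False) -> VolumetricImage:
    """Read a 3D SUV volume from NIfTI; spacing/origin from the header."""
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(img.affine)
    values = np.asarray(img.get_fdata(), dtype=float)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {values.shape}")
    if np.any(values < 0):
        if not clamp_negative:
            raise ValueError(
                f"{path}: negative voxel values found; pass clamp_negative=True "
                "(or --clamp-negative) to clip them to 0"
            )
        values = np.clip(values, 0.0, None)
    return VolumetricImage(values=values, spacing=spacing, origin=origin)


def read_mask(path) -> SegmentationMask:
    """Read a binary mask from NIfTI; values must round to 0/1 within 1e-6."""
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(img.affine)
    values = np.asarray(img.get_fdata(), dtype=float)
    rounded = np.rint(values)
    if np.any(np.abs(values - rounded) > 1e-6) or not np.isin(rounded, (0, 1)).all():
        raise InvalidMaskError(f"{path}: mask is not binary")
    return SegmentationMask(indicator=rounded.astype(bool), spacing=spacing, origin=origin)


def write_volume(path, image: VolumetricImage):
    nib.save(nib.Nifti1Image(image.values, _affine(image.spacing, image.origin)), str(path))


def write_mask(path, mask: SegmentationMask):
    nib.save(
        nib.Nifti1Image(mask.indicator.astype(np.uint8), _affine(mask.spacing, mask.origin)),
        str(path),
    )


def write_density(path, density: DensityManifold):
    nib.save(
        nib.Nifti1Image(density.density, _affine(density.spacing, density.origin)), str(path)
    )


def write_contour_set(out_dir, contour_set: ProbabilityContourSet, stem="contours"):
    """Write a label volume (contours containing each voxel) plus a text table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m0 = contour_set.masks[0]
    nib.save(
        nib.Nifti1Image(contour_set.label_volume(), _affine(m0.spacing, m0.origin)),
        str(out_dir / f"{stem}_labels.nii.gz"),
    )
    table_path = out_dir / f"{stem}_levels.tsv"
    with open(table_path, "w") as fh:
        fh.write("omega\tlambda_omega\tenclosed_mass\tdensity_mass\tvoxels\n")
        for om, lam, em, dm, nvox in contour_set.table():
            fh.write(f"{om:.4f}\t{lam:.8e}\t{em:.6f}\t{dm:.6f}\t{nvox}\n")
    return table_path


def write_surface(path, surface: SurfaceMesh):
    """Export a surface mesh; format chosen from the extension (.obj/.stl)."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces, process=False)
    mesh.export(str(path))


def write_manifest(out_dir, config: dict, name="manifest.json"):
    """Record inputs, configuration and library versions for reproducibility."""
    from importlib.metadata import version

    import scipy
    import skimage

    payload = {
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "nibabel": nib.__version__,
            "click": version("click"),
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
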