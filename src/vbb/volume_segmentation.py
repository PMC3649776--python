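"""From CT-like intensity volumes to bone surface meshes.

The pipeline mirrors the clinical reconstruction workflow: intensity
thresholding classifies voxels as bone (cortical bone is high-intensity on
CT), the largest connected component isolates the bone of interest from
other structures, and marching cubes extracts a triangle mesh in physical
(mm) coordinates.

Conventions: voxel indexing is 0-based; the center of voxel (i, j, k) is at
``origin + index * spacing``; intensity arrays are indexed [x, y, z] in the
world frame of the file header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .errors import EmptyResultWarning, FormatError, ParameterError, PreconditionError, ValidationError
from .mesh_core import SurfaceMesh

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "threshold_segment",
    "largest_component",
    "extract_surface",
    "DEFAULT_BONE_THRESHOLD_HU",
]

# cortical-bone convention for CT-like intensities (HU-equivalent)
DEFAULT_BONE_THRESHOLD_HU = 300.0


@dataclass
class VoxelVolume:
    """3D intensity grid with physical spacing and origin (mm)."""

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3D array")
        if min(self.intensities.shape) < 2:
            raise ValidationError("each volume axis needs >= 2 voxels")
        if (self.spacing_mm <= 0).any():
            raise ValidationError("spacing must be > 0 on every axis")
        if not np.isfinite(self.intensities).all():
            raise ValidationError("intensities contain NaN/inf")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclass
class BinaryMask:
    """Boolean voxel classification sharing geometry with its source volume."""

    mask: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be a 3D array")

    def count(self) -> int:
        return int(self.mask.sum())


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Spacing and origin come from the file header; intensities are returned
    unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(path)
            data = np.asarray(img.dataobj).astype(np.float64)
            affine = img.affine
            spacing = np.linalg.norm(affine[:3, :3], axis=0)
            origin = affine[:3, 3]
        elif name.endswith(".nrrd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
            spacing = np.asarray(img.GetSpacing())
            origin = np.asarray(img.GetOrigin())
        else:
            raise FormatError(f"unrecognized volume format: {path.name}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse volume {path}: {exc}") from exc
    return VoxelVolume(data, spacing, origin)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.spacing_mm)
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), path)
    elif name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.intensities.transpose(2, 1, 0).astype(np.float32))
        img.SetSpacing(tuple(float(s) for s in volume.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in volume.origin_mm))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unrecognized volume format: {path.name}")


def threshold_segment(volume: VoxelVolume, low: float = DEFAULT_BONE_THRESHOLD_HU,
                      high: float = np.inf) -> BinaryMask:
    """Dual-threshold segmentation: voxel is bone iff low <= intensity <= high."""
    if not low < high:
        raise ParameterError(f"low ({low}) must be < high ({high})")
    m = (volume.intensities >= low) & (volume.intensities <= high)
    if not m.any():
        warnings.warn("threshold selects no voxels", EmptyResultWarning, stacklevel=2)
    return BinaryMask(m, volume.spacing_mm, volume.origin_mm)


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the connected component with the most voxels.

    Ties are broken in favor of the component containing the smallest
    linear (C-order flattened) voxel index. Idempotent.
    """
    if connectivity not in (6, 26):
        raise ParameterError("connectivity must be 6 or 26")
    if not mask.mask.any():
        raise PreconditionError("mask is empty: no components to select")
    structure = np.ones((3, 3, 3), bool) if connectivity == 26 \
        else ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(mask.mask, structure=structure)
    if n == 1:
        return BinaryMask(mask.mask.copy(), mask.spacing_mm, mask.origin_mm)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    tied = np.flatnonzero(sizes == best) + 1
    if len(tied) > 1:
        flat = labels.ravel()
        winner = flat[np.flatnonzero(np.isin(flat, tied))[0]]
    else:
        winner = tied[0]
    return BinaryMask(labels == winner, mask.spacing_mm, mask.origin_mm)


def extract_surface(source: BinaryMask | VoxelVolume, iso_level: float | None = None,
                    smoothing_sigma: float = 0.0) -> SurfaceMesh:
    """Marching-cubes isosurface in physical (mm) coordinates.

    For a :class:`BinaryMask` the field is the mask as floats with iso 0.5
    (optionally after Gaussian smoothing, ``smoothing_sigma`` in voxels,
    off by default). For a :class:`VoxelVolume` an explicit ``iso_level``
    strictly inside the intensity range is required. Faces are wound so
    normals point outward (away from the high-intensity interior).
    """
    if isinstance(source, BinaryMask):
        fieldarr = source.mask.astype(np.float32)
        level = 0.5 if iso_level is None else float(iso_level)
    elif isinstance(source, VoxelVolume):
        if iso_level is None:
            raise ParameterError("iso_level is required for intensity volumes")
        fieldarr = source.intensities.astype(np.float32)
        level = float(iso_level)
    else:
        raise ParameterError(f"cannot extract surface from {type(source).__name__}")
    if smoothing_sigma > 0:
        fieldarr = ndimage.gaussian_filter(fieldarr, smoothing_sigma)
    lo, hi = float(fieldarr.min()), float(fieldarr.max())
    if not lo < level < hi:
        raise ParameterError(
            f"iso level {level} not strictly inside field range [{lo}, {hi}]")
    verts, faces, _, _ = marching_cubes(fieldarr, level=level,
                                        spacing=tuple(source.spacing_mm))
    verts = verts + source.origin_mm
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:  # enforce outward winding
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1].copy())
    return mesh
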