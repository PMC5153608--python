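"""Volume and mask containers plus NIfTI-1 input/output.

Conventions used throughout the toolkit:

* voxel indices are 0-based with half-open extents;
* array axes are ordered (x, y, z), matching nibabel's default data layout
  for NIfTI;
* intensities are arbitrary tracer-uptake units stored as float64.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import (
    AnisotropicSpacingError,
    EmptyMaskError,
    NonFiniteDataError,
    NotThreeDimensionalError,
    ShapeMismatchError,
    VolumeError,
)

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "crop_to_mask",
    "mask_bounding_box",
]


@dataclass
class Volume:
    """A 3D scalar field of tracer uptake with voxel spacing in mm.

    Parameters
    ----------
    data:
        3D float array, axes (x, y, z).
    spacing:
        Per-axis voxel size in mm; all components positive.
    affine:
        Optional 4x4 voxel-to-world affine kept so volumes written back to
        disk preserve their spatial frame. Not used by any computation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise NotThreeDimensionalError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if any(s < 1 for s in self.data.shape):
            raise VolumeError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise NonFiniteDataError("volume contains non-finite data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_isotropic(self, rtol: float = 1e-3) -> bool:
        s = np.asarray(self.spacing)
        return bool(np.ptp(s) <= rtol * s.min())


@dataclass
class BinaryMask:
    """A 3D boolean grid with voxel spacing in mm.

    Must contain at least one true voxel.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise NotThreeDimensionalError(
                f"mask data must be 3D, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if not self.data.any():
            raise EmptyMaskError("mask has no true voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(d == 1 for d in data.shape[3:]) else data
    if data.ndim != 3:
        raise NotThreeDimensionalError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), img.affine


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1 volume from disk.

    Raises
    ------
    FileNotFoundError, NotThreeDimensionalError, NonFiniteDataError
    """
    data, spacing, affine = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise NonFiniteDataError(f"{path}: non-finite data")
    return Volume(data=data, spacing=spacing, affine=affine)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, encoding spacing in the header."""
    affine = volume.affine
    if affine is None:
        affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask (any nonzero voxel is true)."""
    data, spacing, _ = _load_nifti(path)
    return BinaryMask(data=data != 0, spacing=spacing)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def mask_bounding_box(mask: BinaryMask) -> tuple[tuple[int, int], ...]:
    """Half-open (lo, hi) extents of the tight bounding box of true voxels."""
    bounds = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.data.any(axis=other)
        idx = np.flatnonzero(profile)
        bounds.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(bounds)


def crop_to_mask(volume: Volume, mask: BinaryMask) -> Volume:
    """Crop a volume to the tight bounding box of a mask.

    Voxels inside the box but outside the mask are zeroed, so only masked
    tissue contributes gradient energy to descriptors computed downstream.
    """
    if volume.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    (x0, x1), (y0, y1), (z0, z1) = mask_bounding_box(mask)
    sub = volume.data[x0:x1, y0:y1, z0:z1].copy()
    sub[~mask.data[x0:x1, y0:y1, z0:z1]] = 0.0
    return Volume(data=sub, spacing=volume.spacing)


def require_isotropic(volume: Volume) -> None:
    """Raise unless the volume's voxels are (near-)isotropic.

    The descriptor mixes gradient components without folding spacing in, so
    anisotropic voxels would silently distort orientations; refusing is
    safer than resampling.
    """
    if not volume.is_isotropic():
        raise AnisotropicSpacingError(
            f"anisotropic spacing {volume.spacing}; resample to isotropic voxels first"
        )
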