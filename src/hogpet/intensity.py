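"""Voxel-intensity comparator features: dilated brain mask, z-normalized.

The baseline classifier treats each image as a point whose coordinates are
the voxel intensities inside a (dilated) brain mask, standardized per image
to zero mean and unit variance so global uptake scaling cancels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, EmptyMaskError, ShapeMismatchError
from .io import BinaryMask, Volume

__all__ = ["dilate_mask", "extract_intensity_features", "ball_structure"]


def ball_structure(radius_voxels: tuple[int, int, int]) -> np.ndarray:
    """Discrete ellipsoidal structuring element with the given voxel radii.

    A voxel offset is included when sum((offset_i / r_i)^2) <= 1; radius 0
    along an axis confines the element to that plane.
    """
    rx, ry, rz = radius_voxels
    grids = np.mgrid[-rx : rx + 1, -ry : ry + 1, -rz : rz + 1].astype(np.float64)
    denom = np.array([max(rx, 1), max(ry, 1), max(rz, 1)], dtype=np.float64)
    dist2 = sum((grids[i] / denom[i]) ** 2 for i in range(3))
    structure = dist2 <= 1.0 + 1e-9
    if rx == 0:
        structure &= grids[0] == 0
    if ry == 0:
        structure &= grids[1] == 0
    if rz == 0:
        structure &= grids[2] == 0
    return structure


def dilate_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Morphologically dilate a mask by a physical radius.

    The radius is converted per axis to voxels (nearest integer, using the
    mask's spacing) and a discrete ball of that size is applied. Radius 0
    returns an identical mask.
    """
    if radius_mm < 0:
        raise ValueError(f"dilation radius must be >= 0, got {radius_mm}")
    radii = tuple(int(round(radius_mm / s)) for s in mask.spacing)
    if all(r == 0 for r in radii):
        return BinaryMask(data=mask.data.copy(), spacing=mask.spacing)
    dilated = ndimage.binary_dilation(mask.data, structure=ball_structure(radii))
    return BinaryMask(data=dilated, spacing=mask.spacing)


def extract_intensity_features(volume: Volume, mask: BinaryMask) -> np.ndarray:
    """Masked voxel intensities, standardized per image.

    Voxels are taken in deterministic x-fastest order (x varies quickest,
    then y, then z) and shifted/scaled to zero mean and unit population
    variance, so feature vectors are invariant to positive affine intensity
    transforms of the image.
    """
    if volume.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    if not mask.data.any():
        raise EmptyMaskError("mask has no true voxels")
    # Fortran raveling makes the x index vary fastest for (x, y, z) arrays.
    flat = volume.data.ravel(order="F")[mask.data.ravel(order="F")]
    std = flat.std()  # population (ddof=0)
    if std == 0:
        raise DegenerateDataError("image is constant within the mask")
    return (flat - flat.mean()) / std
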