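"""Discrete 3D gradients, integral gradient volumes and O(1) cuboid means.

The integral volume (3D summed-area table) stores, at each voxel, the sum
of each gradient component over all voxels with indices no greater than it
along every axis. The mean gradient over any axis-aligned cuboid is then an
eight-corner inclusion-exclusion evaluation divided by the cuboid's voxel
count, independent of cuboid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CuboidOutOfBoundsError, NonFiniteDataError, VolumeError
from .io import Volume

__all__ = [
    "GradientField",
    "IntegralGradientVolume",
    "Cuboid",
    "compute_gradient",
    "build_integral",
    "mean_gradient",
    "mean_gradients",
]


@dataclass
class GradientField:
    """Per-voxel gradient components, same shape as the source volume.

    Units are intensity per voxel: voxel spacing is deliberately not folded
    in, because the descriptor uses only orientation and relative magnitude
    and isotropic voxels are enforced upstream.
    """

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gx.shape == self.gy.shape == self.gz.shape):
            raise VolumeError("gradient components must share one shape")
        for g in (self.gx, self.gy, self.gz):
            if not np.all(np.isfinite(g)):
                raise NonFiniteDataError("gradient field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gx.shape  # type: ignore[return-value]


@dataclass
class Cuboid:
    """Axis-aligned box: origin voxel (x, y, z) and size (w, h, d) >= 1."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.size):
            raise VolumeError(f"cuboid size components must be >= 1, got {self.size}")
        if any(o < 0 for o in self.origin):
            raise CuboidOutOfBoundsError(f"negative origin {self.origin}")

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        for o, s, n in zip(self.origin, self.size, shape):
            if o + s > n:
                raise CuboidOutOfBoundsError(
                    f"cuboid origin={self.origin} size={self.size} exceeds grid {shape}"
                )

    @property
    def n_voxels(self) -> int:
        w, h, d = self.size
        return w * h * d


@dataclass
class IntegralGradientVolume:
    """Cumulative sums of each gradient component over all three axes.

    ``Ix[x, y, z]`` is the sum of gx over every voxel (x', y', z') with
    x' <= x, y' <= y, z' <= z; likewise Iy, Iz. Accumulated in float64.
    """

    Ix: np.ndarray
    Iy: np.ndarray
    Iz: np.ndarray
    _padded: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.Ix.shape  # type: ignore[return-value]

    def padded(self) -> np.ndarray:
        """Zero-padded stack of shape (3, nx+1, ny+1, nz+1) for O(1) lookups."""
        if self._padded is None:
            nx, ny, nz = self.shape
            pad = np.zeros((3, nx + 1, ny + 1, nz + 1))
            for i, comp in enumerate((self.Ix, self.Iy, self.Iz)):
                pad[i, 1:, 1:, 1:] = comp
            self._padded = pad
        return self._padded


def compute_gradient(volume: Volume) -> GradientField:
    """Finite-difference gradient: central in the interior, one-sided at faces.

    Requires every dimension >= 2 (a single slab has no gradient along its
    thin axis).
    """
    if any(n < 2 for n in volume.shape):
        raise VolumeError(f"need every dimension >= 2 for gradients, got {volume.shape}")
    gx, gy, gz = np.gradient(volume.data, edge_order=1)
    return GradientField(gx=gx, gy=gy, gz=gz)


def build_integral(field: GradientField) -> IntegralGradientVolume:
    """Triple cumulative sum of each gradient component (float64)."""
    comps = []
    for g in (field.gx, field.gy, field.gz):
        acc = g.astype(np.float64)
        for axis in range(3):
            acc = np.cumsum(acc, axis=axis)
        comps.append(acc)
    return IntegralGradientVolume(Ix=comps[0], Iy=comps[1], Iz=comps[2])


def _corner_sums(pad: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Inclusion-exclusion sums over boxes [lo, hi) for all components.

    ``lo`` and ``hi`` are (N, 3) integer corner arrays into the padded
    integral stack; returns (N, 3) sums (one row per box, columns gx/gy/gz).
    """
    x0, y0, z0 = lo[:, 0], lo[:, 1], lo[:, 2]
    x1, y1, z1 = hi[:, 0], hi[:, 1], hi[:, 2]
    s = (
        pad[:, x1, y1, z1]
        - pad[:, x0, y1, z1]
        - pad[:, x1, y0, z1]
        + pad[:, x0, y0, z1]
        - pad[:, x1, y1, z0]
        + pad[:, x0, y1, z0]
        + pad[:, x1, y0, z0]
        - pad[:, x0, y0, z0]
    )
    return s.T


def mean_gradients(ivol: IntegralGradientVolume, boxes: list[Cuboid]) -> np.ndarray:
    """Mean gradient vectors for many cuboids at once; returns (N, 3)."""
    if not boxes:
        return np.zeros((0, 3))
    shape = ivol.shape
    for b in boxes:
        b.check_inside(shape)
    lo = np.array([b.origin for b in boxes], dtype=np.intp)
    hi = lo + np.array([b.size for b in boxes], dtype=np.intp)
    sums = _corner_sums(ivol.padded(), lo, hi)
    counts = np.array([b.n_voxels for b in boxes], dtype=np.float64)
    return sums / counts[:, None]


def mean_gradient(ivol: IntegralGradientVolume, box: Cuboid) -> np.ndarray:
    """Mean gradient vector over one cuboid: 8-corner sum / (w*h*d)."""
    return mean_gradients(ivol, [box])[0]
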