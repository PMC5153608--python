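"""3D histogram-of-oriented-gradients descriptor for brain volumes.

The volume is partitioned into a uniform grid of k*k*k-voxel cells (partial
edge cells are discarded symmetrically). Each cell is split into S*S*S
sub-blocks; the mean gradient of every sub-block is read from the shared
integral gradient volume in constant time, quantized onto polyhedron face
bins, and the sub-block votes are summed into the cell histogram. Cell
histograms concatenate (x-fastest cell order, bins contiguous per cell)
into the volume's feature vector.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import VolumeError
from .gradients import Cuboid, IntegralGradientVolume, build_integral, compute_gradient, mean_gradient
from .io import Volume, require_isotropic
from .orientation import N_FACES, OrientationPolyhedron, make_polyhedron, quantize_gradients

__all__ = [
    "HOGParams",
    "FeatureVector",
    "partition_cells",
    "cell_histogram",
    "extract_descriptor",
    "enumerate_param_grid",
    "descriptor_length",
    "features_to_frame",
    "save_feature_matrix",
    "load_feature_matrix",
]


@dataclass(frozen=True)
class HOGParams:
    """Descriptor parameters.

    Defaults are the configuration found optimal on florbetapir training
    data: 16-voxel cells, one sub-block, icosahedron bins, half-orientation.

    Attributes
    ----------
    k:
        Cell edge length in voxels (>= 1, divisible by S).
    S:
        Sub-blocks per axis within a cell; one of {1, 2, 4}.
    polyhedron:
        "dodecahedron" or "icosahedron".
    half:
        Fold antipodal gradient directions into shared bins.
    normalize_cells:
        Optional per-cell L2 normalization (off by default: the magnitude
        weighting of the quantizer is the only weighting applied).
    concat_subblocks:
        Alternative layout that concatenates the S^3 sub-block votes instead
        of summing them within the cell.
    """

    k: int = 16
    S: int = 1
    polyhedron: str = "icosahedron"
    half: bool = True
    normalize_cells: bool = False
    concat_subblocks: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise VolumeError(f"cell size k must be >= 1, got {self.k}")
        if self.S not in (1, 2, 4):
            raise VolumeError(f"sub-blocks per axis S must be in {{1,2,4}}, got {self.S}")
        if self.k % self.S != 0:
            raise VolumeError(f"k={self.k} must be divisible by S={self.S}")

    @property
    def n_bins(self) -> int:
        n = N_FACES[self.polyhedron]
        return n // 2 if self.half else n

    def make_quantizer(self) -> OrientationPolyhedron:
        return make_polyhedron(self.polyhedron, half=self.half)


@dataclass
class FeatureVector:
    """Concatenated per-cell orientation histograms for one volume."""

    values: np.ndarray
    grid_shape: tuple[int, int, int]
    n_bins: int
    params: HOGParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("feature vector contains non-finite values")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid_shape))

    def __len__(self) -> int:
        return self.values.size


def partition_cells(shape: tuple[int, int, int], k: int) -> list[Cuboid]:
    """Uniform grid of k^3 cells with symmetric margins.

    Each axis holds floor(dim/k) cells anchored at offset (dim mod k)//2, so
    any voxels that do not fill a whole cell are discarded evenly from both
    ends. Cells are returned x-fastest: flat index = ix + nx*(iy + ny*iz).
    """
    if any(n < k for n in shape):
        raise VolumeError(f"every extent of {shape} must be >= cell size {k}")
    counts = [n // k for n in shape]
    offsets = [(n % k) // 2 for n in shape]
    cells = []
    for iz in range(counts[2]):
        for iy in range(counts[1]):
            for ix in range(counts[0]):
                origin = (
                    offsets[0] + ix * k,
                    offsets[1] + iy * k,
                    offsets[2] + iz * k,
                )
                cells.append(Cuboid(origin=origin, size=(k, k, k)))
    return cells


def _subblocks(cell: Cuboid, S: int) -> list[Cuboid]:
    m = cell.size[0] // S
    blocks = []
    for bz in range(S):
        for by in range(S):
            for bx in range(S):
                origin = (
                    cell.origin[0] + bx * m,
                    cell.origin[1] + by * m,
                    cell.origin[2] + bz * m,
                )
                blocks.append(Cuboid(origin=origin, size=(m, m, m)))
    return blocks


def cell_histogram(
    ivol: IntegralGradientVolume,
    cell: Cuboid,
    params: HOGParams,
    poly: OrientationPolyhedron,
) -> np.ndarray:
    """Sum of quantized mean sub-block gradients for one cell."""
    cell.check_inside(ivol.shape)
    blocks = _subblocks(cell, params.S)
    grads = np.array([mean_gradient(ivol, b) for b in blocks])
    votes = quantize_gradients(grads, poly)
    return votes.sum(axis=0)


def extract_descriptor(volume: Volume, params: HOGParams | None = None) -> FeatureVector:
    """Extract the 3D HOG feature vector of a whole volume.

    The gradient field and its integral volume are built once; every
    sub-block mean then costs eight lookups. Requires isotropic voxels.
    """
    params = params or HOGParams()
    require_isotropic(volume)
    if any(n < params.k for n in volume.shape):
        raise VolumeError(
            f"volume shape {volume.shape} smaller than cell size {params.k}"
        )
    poly = params.make_quantizer()
    ivol = build_integral(compute_gradient(volume))
    cells = partition_cells(volume.shape, params.k)
    grid_shape = tuple(n // params.k for n in volume.shape)

    from .gradients import mean_gradients  # local alias for the batched path

    all_blocks = [b for cell in cells for b in _subblocks(cell, params.S)]
    grads = mean_gradients(ivol, all_blocks)
    votes = quantize_gradients(grads, poly)  # (n_cells*S^3, n_bins)
    per_cell = votes.reshape(len(cells), params.S**3, poly.n_bins)

    if params.concat_subblocks:
        hist = per_cell.reshape(len(cells), -1)
    else:
        hist = per_cell.sum(axis=1)

    if params.normalize_cells:
        norms = np.linalg.norm(hist, axis=1, keepdims=True)
        hist = hist / (norms + 1e-12)

    return FeatureVector(
        values=hist.ravel(),
        grid_shape=grid_shape,  # type: ignore[arg-type]
        n_bins=hist.shape[1],
        params=params,
    )


def descriptor_length(shape: tuple[int, int, int], params: HOGParams) -> int:
    """Predicted feature-vector length: prod(floor(dim/k)) * n_bins."""
    n_cells = int(np.prod([n // params.k for n in shape]))
    bins = params.n_bins * (params.S**3 if params.concat_subblocks else 1)
    return n_cells * bins


def enumerate_param_grid() -> list[HOGParams]:
    """The full descriptor parameter grid searched during optimisation.

    k in {4, 8, ..., 32}, S in {1, 2, 4}, both polyhedra, both orientation
    modes: 8 * 3 * 2 * 2 = 96 combinations, in deterministic order.
    """
    grid = []
    for k, S, kind, half in itertools.product(
        range(4, 36, 4), (1, 2, 4), ("dodecahedron", "icosahedron"), (False, True)
    ):
        grid.append(HOGParams(k=k, S=S, polyhedron=kind, half=half))
    return grid


def _column_names(grid_shape: tuple[int, int, int], n_bins: int) -> list[str]:
    names = []
    nx, ny, nz = grid_shape
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                for b in range(n_bins):
                    names.append(f"cell_{ix}_{iy}_{iz}_bin_{b}")
    return names


def features_to_frame(
    features: list[FeatureVector], subject_ids: list[str] | None = None
) -> pd.DataFrame:
    """Stack per-volume descriptors into a subjects-by-features DataFrame."""
    if not features:
        raise ValueError("no feature vectors given")
    ref = features[0]
    for f in features[1:]:
        if f.grid_shape != ref.grid_shape or len(f) != len(ref):
            raise VolumeError("feature vectors have inconsistent layouts")
    ids = subject_ids or [f"subject_{i}" for i in range(len(features))]
    mat = np.vstack([f.values for f in features])
    cols = _column_names(ref.grid_shape, len(ref) // ref.n_cells)
    return pd.DataFrame(mat, index=pd.Index(ids, name="subject"), columns=cols)


def save_feature_matrix(
    features: list[FeatureVector],
    csv_path: str,
    subject_ids: list[str] | None = None,
) -> None:
    """Write a feature CSV plus a JSON sidecar describing the layout."""
    frame = features_to_frame(features, subject_ids)
    frame.to_csv(csv_path)
    ref = features[0]
    sidecar = {
        "grid_shape": list(ref.grid_shape),
        "n_bins": ref.n_bins,
        "params": None
        if ref.params is None
        else {
            "k": ref.params.k,
            "S": ref.params.S,
            "polyhedron": ref.params.polyhedron,
            "half": ref.params.half,
            "normalize_cells": ref.params.normalize_cells,
            "concat_subblocks": ref.params.concat_subblocks,
        },
    }
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_feature_matrix(csv_path: str) -> pd.DataFrame:
    return pd.read_csv(csv_path, index_col=0)
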