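"""Synthetic amyloid-PET phantoms with ground-truth labels and regions.

The phantom emulates the image property that separates amyloid-positive
from amyloid-negative scans: in a negative scan, white matter retains
tracer while cortical grey matter does not, giving strong grey/white
contrast; amyloid deposition raises cortical uptake, locally erasing that
contrast. Geometry is idealized, not anatomical: an ellipsoidal
white-matter core inside a grey-matter shell inside an ellipsoidal brain
mask, six angular cortical target sectors in the superior shell (mirroring
the six-region composite-SUVR layout), and an inferior cerebellum-like
reference blob at grey-matter intensity. On top of the structure the
generator applies a Gaussian point-spread blur, a smooth multiplicative
bias field and additive Gaussian noise, all seeded.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import VolumeError
from .io import BinaryMask, Volume, write_mask, write_volume
from .suvr import RegionSet, composite_suvr

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
]

RNG_ALGORITHM = "PCG64"

TARGET_NAMES = (
    "frontal",
    "parietal",
    "anterior_cingulate",
    "posterior_cingulate",
    "precuneus",
    "temporal",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scan.

    Attributes
    ----------
    shape:
        Grid extents in voxels; default 80x96x80 at 2 mm, the common
        spatially normalized amyloid-PET matrix.
    spacing_mm:
        Isotropic voxel size.
    wm_intensity, gm_intensity:
        White/grey-matter uptake in arbitrary units; GM < WM gives the
        amyloid-negative contrast.
    reference_intensity:
        Uptake of the cerebellar-grey-like reference blob; defaults to the
        grey-matter value so a negative scan has composite SUVR near 1.
    uptake_factor:
        Multiplier applied to cortical target sectors; 1.0 produces an
        amyloid-negative scan, values > 1 erase grey/white contrast and
        label the phantom positive (default 1.5).
    psf_fwhm_mm:
        Gaussian point-spread FWHM (default 8 mm, clinical amyloid PET).
    bias_amplitude:
        Peak fractional amplitude of the smooth multiplicative bias field
        (default 0.10, i.e. +/-10%).
    noise_sd:
        Additive Gaussian noise standard deviation in intensity units.
    seed:
        Seed for the per-phantom random stream (PCG64).
    """

    shape: tuple[int, int, int] = (80, 96, 80)
    spacing_mm: float = 2.0
    wm_intensity: float = 1.8
    gm_intensity: float = 1.0
    reference_intensity: float | None = None
    uptake_factor: float = 1.5
    psf_fwhm_mm: float = 8.0
    bias_amplitude: float = 0.10
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise VolumeError(f"phantom grid too small: {self.shape}")
        if self.wm_intensity <= 0 or self.gm_intensity <= 0:
            raise VolumeError("tissue intensities must be positive")
        if self.uptake_factor < 1.0:
            raise VolumeError("uptake factor must be >= 1")
        if self.psf_fwhm_mm < 0:
            raise VolumeError("PSF FWHM must be >= 0")
        if not 0.0 <= self.bias_amplitude <= 0.5:
            raise VolumeError("bias amplitude must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise VolumeError("noise sd must be >= 0")

    @property
    def is_positive(self) -> bool:
        return self.uptake_factor > 1.0

    @property
    def ref_intensity(self) -> float:
        return self.gm_intensity if self.reference_intensity is None else self.reference_intensity


@dataclass
class PhantomBundle:
    """One synthetic scan plus everything needed to analyse it."""

    volume: Volume
    brain_mask: BinaryMask
    regions: RegionSet
    label_map: np.ndarray
    label_names: dict[str, int]
    amyloid_positive: bool
    true_composite_suvr: float
    metadata: dict = field(default_factory=dict)


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    d2 = sum(((grids[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _bias_field(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f, max|f| = 1.

    f is a sum of three low-frequency cosine waves with random directions
    and phases, so the field varies slowly across the whole grid.
    """
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    for i in range(3):
        grids[i] /= shape[i]
    f = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        freq = rng.uniform(0.5, 1.5)  # cycles across the grid
        phase = rng.uniform(0, 2 * np.pi)
        proj = sum(direction[i] * grids[i] for i in range(3))
        f += np.cos(2 * np.pi * freq * proj + phase)
    peak = np.max(np.abs(f))
    if peak > 0:
        f /= peak
    return 1.0 + amplitude * f


def _build_geometry(
    shape: tuple[int, int, int], axis_jitter: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Brain mask, WM core, six target sectors, reference blob."""
    shape_arr = np.asarray(shape, dtype=np.float64)
    center = (shape_arr - 1) / 2.0
    brain_axes = shape_arr * np.array([0.42, 0.44, 0.42]) + axis_jitter
    wm_axes = brain_axes * 0.60
    brain = _ellipsoid(shape, center, brain_axes)
    wm = _ellipsoid(shape, center, wm_axes)
    gm = brain & ~wm

    # Reference blob: inferior-posterior, grey-matter-like, inside the brain.
    ref_center = center + np.array([0.0, -0.40 * brain_axes[1], -0.55 * brain_axes[2]])
    ref_axes = np.array([0.28, 0.22, 0.20]) * brain_axes
    reference = _ellipsoid(shape, ref_center, ref_axes) & brain

    # Six angular cortical sectors in the superior grey-matter shell.
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    superior = grids[2] > center[2] + 1.0
    azimuth = np.arctan2(grids[1] - center[1], grids[0] - center[0])  # [-pi, pi)
    sector_idx = np.floor((azimuth + np.pi) / (2 * np.pi / 6)).astype(int)
    sector_idx = np.clip(sector_idx, 0, 5)
    targets = np.where(gm & superior & ~reference, sector_idx + 1, 0)
    return brain, wm, targets, reference


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate one phantom from a spec, fully determined by its seed.

    The random stream is consumed in a fixed order (geometry never draws;
    bias first, then noise) regardless of the uptake factor, so two specs
    differing only in ``uptake_factor`` but sharing a seed produce volumes
    that differ only through the uptake change.
    """
    return _generate_with_axis_jitter(spec, np.zeros(3))


def _regions_from(
    label_map: np.ndarray, names: dict[str, int], spacing: tuple[float, float, float]
) -> RegionSet:
    targets = {
        name: BinaryMask(data=label_map == lbl, spacing=spacing)
        for name, lbl in names.items()
        if name != "reference"
    }
    reference = BinaryMask(data=label_map == names["reference"], spacing=spacing)
    return RegionSet(targets=targets, reference=reference, tracer="florbetapir")


def _jittered_spec(base: PhantomSpec, positive: bool, rng: np.random.Generator) -> tuple[PhantomSpec, np.ndarray]:
    """Per-subject spec: +/-10% tissue intensities, +/-1 voxel brain axes."""
    jit = rng.uniform(-0.1, 0.1, size=3)
    axis_jitter = rng.uniform(-1.0, 1.0, size=3)
    child_seed = int(rng.integers(0, 2**31 - 1))
    spec = PhantomSpec(
        shape=base.shape,
        spacing_mm=base.spacing_mm,
        wm_intensity=base.wm_intensity * (1 + jit[0]),
        gm_intensity=base.gm_intensity * (1 + jit[1]),
        reference_intensity=base.ref_intensity * (1 + jit[1]),  # tracks GM
        uptake_factor=base.uptake_factor if positive else 1.0,
        psf_fwhm_mm=base.psf_fwhm_mm,
        bias_amplitude=base.bias_amplitude,
        noise_sd=base.noise_sd,
        seed=child_seed,
    )
    return spec, axis_jitter


def generate_cohort(
    n_pos: int,
    n_neg: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[PhantomBundle], list[bool]]:
    """Generate a labelled cohort with per-subject anatomical jitter.

    Positive subjects use the spec's uptake factor; negative subjects use
    1.0. Returns the bundles (positives first) and their labels.
    """
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    bundles: list[PhantomBundle] = []
    labels: list[bool] = []
    for positive in [True] * n_pos + [False] * n_neg:
        sub_spec, axis_jitter = _jittered_spec(base, positive, rng)
        bundle = _generate_with_axis_jitter(sub_spec, axis_jitter)
        bundles.append(bundle)
        labels.append(positive)
    return bundles, labels


def _generate_with_axis_jitter(spec: PhantomSpec, axis_jitter: np.ndarray) -> PhantomBundle:
    """generate_phantom with jittered ellipsoid axes (cohort variability)."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    brain, wm, targets, reference = _build_geometry(shape, axis_jitter)

    structure = np.zeros(shape, dtype=np.float64)
    structure[brain] = spec.gm_intensity
    structure[wm] = spec.wm_intensity
    structure[reference] = spec.ref_intensity
    structure[targets > 0] *= spec.uptake_factor

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.spacing_mm
        clean = ndimage.gaussian_filter(structure, sigma=sigma_vox)
    else:
        clean = structure

    spacing = (spec.spacing_mm,) * 3
    label_map = np.where(reference, 7, targets).astype(np.int16)
    names = {name: i + 1 for i, name in enumerate(TARGET_NAMES)}
    names["reference"] = 7
    regions = _regions_from(label_map, names, spacing)
    true_suvr = composite_suvr(
        Volume(data=clean, spacing=spacing), regions, threshold=1.0
    ).composite

    bias = _bias_field(shape, spec.bias_amplitude, rng)
    noisy = clean * bias + rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else clean * bias

    return PhantomBundle(
        volume=Volume(data=noisy, spacing=spacing),
        brain_mask=BinaryMask(data=brain, spacing=spacing),
        regions=regions,
        label_map=label_map,
        label_names=names,
        amyloid_positive=spec.is_positive,
        true_composite_suvr=true_suvr,
        metadata={
            "rng": RNG_ALGORITHM,
            "seed": spec.seed,
            "axis_jitter": axis_jitter.tolist(),
            "spec": asdict(spec),
        },
    )


def save_cohort(bundles: list[PhantomBundle], labels: list[bool], out_dir: str) -> None:
    """Write a cohort to disk: NIfTI volumes, label maps, labels CSV, specs."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (bundle, label) in enumerate(zip(bundles, labels)):
        sid = f"phantom_{i:03d}"
        write_volume(bundle.volume, os.path.join(out_dir, f"{sid}.nii.gz"))
        write_mask(bundle.brain_mask, os.path.join(out_dir, f"{sid}_brainmask.nii.gz"))
        affine = np.diag(list(bundle.volume.spacing) + [1.0])
        nib.save(
            nib.Nifti1Image(bundle.label_map.astype(np.int16), affine),
            os.path.join(out_dir, f"{sid}_regions.nii.gz"),
        )
        with open(os.path.join(out_dir, f"{sid}_spec.json"), "w") as fh:
            json.dump(bundle.metadata, fh, indent=2)
        rows.append((sid, int(label)))
    with open(os.path.join(out_dir, "labels.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "amyloid_positive"])
        writer.writerows(rows)
    with open(os.path.join(out_dir, "region_names.json"), "w") as fh:
        json.dump(bundles[0].label_names if bundles else {}, fh, indent=2)
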