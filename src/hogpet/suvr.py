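"""Standardised uptake value ratios (SUVR) and cross-scale thresholds.

A regional SUVR is the mean tracer uptake in a target region divided by the
mean uptake in a reference region (cerebellum-based for amyloid tracers);
the composite SUVR averages the regional values. Amyloid positivity is a
strict threshold on the composite, with tracer- and scale-specific cut
points. Published regressions convert a threshold between quantification
scales; the combined Jagust-to-sPAP map is evaluated by exact composition
of the two published affine fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError, SUVRError
from .io import BinaryMask, Volume

__all__ = [
    "TRACER_THRESHOLDS",
    "RegionSet",
    "SUVRReport",
    "AffineThresholdMap",
    "JAGUST_TO_JOSHI",
    "JOSHI_TO_SPAP",
    "regional_suvr",
    "composite_suvr",
    "jagust_to_joshi",
    "joshi_to_spap",
    "jagust_to_spap",
    "jagust_to_spap_coefficients",
    "regions_from_labels",
]

# Published composite-SUVR positivity thresholds (strict >).
TRACER_THRESHOLDS: dict[str, float] = {
    "florbetapir": 1.12,
    "florbetaben": 1.36,
    "pib_spap": 1.15,
}


@dataclass(frozen=True)
class AffineThresholdMap:
    """Strictly increasing affine map between quantification scales."""

    slope: float
    intercept: float
    source: str
    destination: str

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("threshold maps must be strictly increasing")

    def __call__(self, t: float) -> float:
        return self.slope * t + self.intercept

    def compose(self, inner: "AffineThresholdMap") -> "AffineThresholdMap":
        """self o inner: apply ``inner`` first."""
        return AffineThresholdMap(
            slope=self.slope * inner.slope,
            intercept=self.slope * inner.intercept + self.intercept,
            source=inner.source,
            destination=self.destination,
        )


JAGUST_TO_JOSHI = AffineThresholdMap(0.67, 0.15, "jagust", "joshi")
JOSHI_TO_SPAP = AffineThresholdMap(0.9782, 0.04264, "joshi", "spap")


def jagust_to_joshi(t: float) -> float:
    """Convert a PiB threshold from the Jagust scale to the Joshi scale."""
    return JAGUST_TO_JOSHI(t)


def joshi_to_spap(t: float) -> float:
    """Convert a threshold from the Joshi scale to the sPAP scale."""
    return JOSHI_TO_SPAP(t)


def jagust_to_spap(t: float) -> float:
    """Jagust-to-sPAP threshold conversion by exact composition.

    Evaluates joshi_to_spap(jagust_to_joshi(t)) with full-precision
    coefficients; the conventionally printed rounded coefficients are
    available from :func:`jagust_to_spap_coefficients`.
    """
    return JOSHI_TO_SPAP.compose(JAGUST_TO_JOSHI)(t)


def jagust_to_spap_coefficients(decimals: int = 4) -> tuple[float, float]:
    """(slope, intercept) of the composed map, rounded for reporting."""
    m = JOSHI_TO_SPAP.compose(JAGUST_TO_JOSHI)
    return round(m.slope, decimals), round(m.intercept, decimals)


@dataclass
class RegionSet:
    """Named target masks plus one reference mask for SUVR computation.

    Every mask must be nonempty, share the volume's shape, and the
    reference must be disjoint from each target.
    """

    targets: dict[str, BinaryMask]
    reference: BinaryMask
    tracer: str = "florbetapir"

    def __post_init__(self) -> None:
        if not self.targets:
            raise SUVRError("region set needs at least one target region")
        for name, mask in self.targets.items():
            if mask.shape != self.reference.shape:
                raise ShapeMismatchError(f"target {name!r} shape differs from reference")
            if np.any(mask.data & self.reference.data):
                raise SUVRError(f"target {name!r} overlaps the reference region")


@dataclass
class SUVRReport:
    """Per-region and composite SUVRs plus the threshold decision."""

    regional: dict[str, float]
    composite: float
    threshold: float
    positive: bool
    tracer: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "tracer": self.tracer,
                "regional_suvr": self.regional,
                "composite_suvr": self.composite,
                "threshold": self.threshold,
                "amyloid_positive": self.positive,
            },
            indent=2,
        )


def _mask_mean(volume: Volume, mask: BinaryMask) -> float:
    if volume.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    return float(volume.data[mask.data].mean())


def regional_suvr(volume: Volume, target: BinaryMask, reference: BinaryMask) -> float:
    """Mean uptake over the target divided by mean uptake over the reference."""
    ref_mean = _mask_mean(volume, reference)
    if ref_mean <= 0:
        raise SUVRError(f"reference mean must be positive, got {ref_mean}")
    return _mask_mean(volume, target) / ref_mean


def composite_suvr(
    volume: Volume,
    regions: RegionSet,
    threshold: float | None = None,
    volume_weighted: bool = False,
) -> SUVRReport:
    """Composite SUVR over a region set and the strict-threshold decision.

    The composite is the unweighted mean of regional SUVRs by default;
    ``volume_weighted`` instead weights each region by its voxel count.
    A composite exactly equal to the threshold is negative (strict >).
    """
    if threshold is None:
        if regions.tracer not in TRACER_THRESHOLDS:
            raise SUVRError(
                f"no default threshold for tracer {regions.tracer!r}; pass one explicitly"
            )
        threshold = TRACER_THRESHOLDS[regions.tracer]
    regional = {
        name: regional_suvr(volume, mask, regions.reference)
        for name, mask in regions.targets.items()
    }
    if volume_weighted:
        weights = np.array([regions.targets[n].count() for n in regional])
        composite = float(np.average(list(regional.values()), weights=weights))
    else:
        composite = float(np.mean(list(regional.values())))
    return SUVRReport(
        regional=regional,
        composite=composite,
        threshold=float(threshold),
        positive=composite > threshold,
        tracer=regions.tracer,
    )


def regions_from_labels(
    label_data: np.ndarray,
    name_map: dict[str, int],
    reference_name: str,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tracer: str = "florbetapir",
) -> RegionSet:
    """Build a RegionSet from an integer label volume and a name->label map."""
    if reference_name not in name_map:
        raise SUVRError(f"reference region {reference_name!r} not in name map")
    masks = {
        name: BinaryMask(data=label_data == lbl, spacing=spacing)
        for name, lbl in name_map.items()
    }
    reference = masks.pop(reference_name)
    return RegionSet(targets=masks, reference=reference, tracer=tracer)
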