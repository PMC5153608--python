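"""Exception hierarchy for hogpet.

Every error contract in the toolkit raises one of these named types so
callers can distinguish bad inputs from bugs.
"""


class HogpetError(Exception):
    """Base class for all hogpet errors."""


class VolumeError(HogpetError):
    """Problems with volume data or geometry."""


class NonFiniteDataError(VolumeError):
    """Volume contains NaN or infinite voxels."""


class NotThreeDimensionalError(VolumeError):
    """Image on disk is not a 3D volume."""


class AnisotropicSpacingError(VolumeError):
    """Voxel spacing differs between axes; the descriptor assumes isotropy."""


class EmptyMaskError(VolumeError):
    """A binary mask contains no true voxels."""


class ShapeMismatchError(VolumeError):
    """Mask and volume shapes differ."""


class CuboidOutOfBoundsError(HogpetError):
    """Requested cuboid does not lie inside the grid."""


class UnsupportedPolyhedronError(HogpetError):
    """Orientation quantizer requested for an unsupported solid."""


class DegenerateDataError(HogpetError):
    """Training data cannot support a classifier (e.g. constant features)."""


class ClassBalanceError(HogpetError):
    """A class is missing or too small for the requested procedure."""


class SUVRError(HogpetError):
    """Invalid SUVR computation (empty region, non-positive reference mean)."""
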