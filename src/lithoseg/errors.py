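"""Exception hierarchy.

Every failure mode named by the public API raises a subclass of
:class:`LithosegError`, so callers can catch the package root.
"""


class LithosegError(Exception):
    """Base class for all lithoseg errors."""


class InvalidSpecError(LithosegError):
    """A stone specification violates its invariants (unknown family, bad radii)."""


class OutOfBoundsError(LithosegError):
    """A shape extends outside the rasterization grid."""


class PlacementError(LithosegError):
    """Stones could not be placed without annotation-sphere overlap."""


class EmptyRoiError(LithosegError):
    """An annotation sphere contains no voxel centers."""


class EmptySegmentationError(LithosegError):
    """No voxel survives the threshold inside the annotation region."""


class EmptyMaskError(LithosegError):
    """A morphometry operation received an empty mask."""


class DegenerateCorrectionError(LithosegError):
    """Partial-volume correction drove the volume to zero or below."""


class AlignmentError(LithosegError):
    """Estimate and reference stone ids do not match one-to-one."""


class OptimizationInfeasibleError(LithosegError):
    """Every candidate parameter left every stone unsegmented."""


class ConfigurationError(LithosegError):
    """A run configuration field violates a module invariant."""


class SchemaError(LithosegError):
    """An input file does not conform to its declared schema."""


class FormatError(LithosegError):
    """An image file is readable but not a 3D volume."""


class UndefinedICCError(LithosegError):
    """ICC is undefined (no variance in either measurement set)."""


class DegenerateVarianceError(LithosegError):
    """A Bartlett group has zero variance."""


class InsufficientDataError(LithosegError):
    """Too few paired observations for the requested statistic."""
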