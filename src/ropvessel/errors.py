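"""Exception taxonomy for the vessel-measurement pipeline.

Every pipeline error derives from :class:`RopVesselError` so callers can
catch the whole family; most are also ``ValueError`` subclasses because
they signal bad inputs rather than internal faults.
"""


class RopVesselError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(RopVesselError, ValueError):
    """Malformed or out-of-contract input (empty image, bad axis, ...)."""


class OutOfBoundsError(InvalidInputError):
    """A point (seed, target, profile center) falls outside the valid
    image region, including any sampling margin."""


class NoVesselError(RopVesselError):
    """The directional-profile dynamic range at a seed is below the noise
    floor: there is no detectable vessel contrast to track."""


class LowContrastError(RopVesselError):
    """An edge profile has insufficient center-to-background contrast for
    edge localization; the position is skipped upstream."""


class EndpointError(InvalidInputError):
    """An operation requiring a local tangent was asked at a trace
    endpoint where no tangent is defined."""


class InsufficientMeasurementError(RopVesselError):
    """Fewer than the minimum number of valid width positions survived."""


class MissingMeasurementError(RopVesselError):
    """Both superior and inferior width measurements are absent."""


class EmptyMeasurementError(RopVesselError):
    """No vessel pair in the annotation could be measured."""


class DegenerateFitError(RopVesselError):
    """Line fit requested on coincident points."""


class ParallelLinesError(RopVesselError):
    """Two vessel rays are parallel within tolerance; no intersection."""


class UndefinedCorrelationError(InvalidInputError):
    """Pearson correlation requested on a zero-variance variable."""


class InvalidSpecError(InvalidInputError):
    """A phantom or cohort specification fails validation."""


class FormatError(RopVesselError):
    """An image or annotation file is unreadable or unsupported."""


class InsufficientGroupsError(InvalidInputError):
    """Fewer than two stage groups present in a cohort analysis."""
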