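"""Exception hierarchy for lipospec.

All package errors derive from :class:`LipospecError` so callers can catch
one base class at pipeline boundaries.
"""


class LipospecError(Exception):
    """Base class for all lipospec errors."""


class SpectrumFormatError(LipospecError):
    """A spectrum file could not be parsed under the declared dialect."""


class SpectrumIOError(LipospecError):
    """A spectrum file could not be read from or written to disk."""


class ReferencingError(LipospecError):
    """No local maximum found in the referencing search window."""


class WindowRangeError(LipospecError):
    """An integration window falls outside the spectrum axis."""


class ResolutionError(LipospecError):
    """Too few samples inside a window for a reliable integral or fit."""


class EstimationError(LipospecError):
    """A lineshape parameter (e.g. FWHM) could not be estimated."""


class AcquisitionError(LipospecError):
    """A measured area required for a ratio is zero or unusable."""


class ConfigurationError(LipospecError):
    """Missing or inconsistent configuration (standards, measurands...)."""


class MetadataError(LipospecError):
    """Sample metadata missing a field required by the requested operation."""


class InsufficientDataError(LipospecError):
    """Fewer observations than the statistical operation requires."""


class UndefinedStatisticError(LipospecError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
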