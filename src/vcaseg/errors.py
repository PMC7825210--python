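"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2, IOFailure -> 3,
anything else -> 4.
"""


class VcasegError(Exception):
    """Base class for all package errors."""


class ValidationError(VcasegError, ValueError):
    """Invalid parameters, configuration, or input contracts."""


class IOFailure(VcasegError, OSError):
    """Unreadable, unwritable, or unsupported files."""


class UnsupportedFormatError(IOFailure):
    """File extension outside the supported raster formats."""


class ShapeError(ValidationError):
    """Array with the wrong number of channels or dimensions."""


class BoundsError(ValidationError):
    """Coordinates or ROI outside the host image."""


class DegenerateImageError(ValidationError):
    """Histogram with a single occupied bin; no threshold can split it."""


class ConsistencyError(ValidationError):
    """Skeleton/mask pair violating the skeleton-subset-of-mask contract."""


class SampleSizeError(ValidationError):
    """Statistical routine called with too few observations."""


class DegenerateDataError(ValidationError):
    """Statistic undefined (for instance both groups constant and equal)."""


class MissingDayError(ValidationError):
    """A study day required by the analysis is absent for every subject."""
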