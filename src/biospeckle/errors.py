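"""Exception hierarchy.

Numerical degeneracies (zero-variance frames, empty groups, impossible
normalizations) raise loudly instead of propagating NaN into averaged
curves and test statistics.
"""


class BiospeckleError(Exception):
    """Base class for all package errors."""


class ConfigError(BiospeckleError):
    """Invalid or incomplete run configuration."""


class InvalidGeometryError(ConfigError):
    """Optical geometry with non-positive or inconsistent dimensions."""


class UndersamplingError(ConfigError):
    """Requested speckle size below the two-pixel sampling limit."""


class DataError(BiospeckleError):
    """Problems with stored or supplied data."""


class CorruptFileError(DataError):
    """Stored payload inconsistent with its declared dimensions."""


class DegenerateFrameError(DataError):
    """A frame with zero variance where a correlation is required."""


class NumericError(BiospeckleError):
    """Analysis-stage numerical failure."""


class WindowError(NumericError):
    """An analysis window longer than the curve it is applied to."""


class EstimationFailureError(NumericError):
    """An estimator could not bracket or converge to a value."""


class NormalizationError(NumericError):
    """Non-positive control value in a ratio normalization."""


class SampleSizeError(NumericError):
    """Too few replicates for the requested statistical test."""


class GroupingError(NumericError):
    """Empty or missing group in a grouped aggregation."""


class BaselineError(NumericError):
    """Missing pre-exposure baseline measurements."""
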