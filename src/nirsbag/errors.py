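"""Typed exception hierarchy.

Every validation failure in the package raises one of these, so callers
(and the CLI exit-code mapping) can distinguish bad configuration from
bad data from a computation that could not proceed.
"""


class NirsbagError(Exception):
    """Base class for all package errors."""


class ConfigError(NirsbagError):
    """Invalid configuration or parameter specification."""


class FormatError(NirsbagError):
    """On-disk file does not match the expected dialect."""


class SamplingError(NirsbagError):
    """Timestamps incompatible with a uniform sampling grid."""


class DataError(NirsbagError):
    """Non-finite or otherwise invalid numeric data."""


class OrderingError(NirsbagError):
    """Event onsets not monotone non-decreasing."""


class PairingError(NirsbagError):
    """Channels cannot be grouped into the required wavelength or
    chromophore pairs."""


class ParameterError(ConfigError):
    """A numeric parameter is out of its valid domain (e.g. singular
    extinction matrix, non-positive path length)."""


class FilterSpecError(ConfigError):
    """Band edges incompatible with the sampling rate."""


class BoundaryError(NirsbagError):
    """An epoch window extends beyond the recording."""


class IntervalError(ConfigError):
    """A requested time interval is not contained in its parent window."""


class SampleSizeError(DataError):
    """Too few samples (or samples per class) for the requested fit."""


class ShapeError(DataError):
    """Array dimensions do not match the model."""


class ModelError(NirsbagError):
    """A model object is unusable (e.g. empty ensemble)."""


class DomainError(ConfigError):
    """A scalar argument outside its mathematical domain
    (accuracy not in [0, 1], alpha not in (0, 1), ...)."""


class StratificationError(NirsbagError):
    """A class has fewer members than the number of folds."""


class DegenerateDataError(DataError):
    """A statistic is undefined on this input (zero variance)."""


class ComputationError(NirsbagError):
    """A pipeline stage failed mid-run; carries stage context."""
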