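"""Exception hierarchy for drnaprof."""


class DrnaprofError(Exception):
    """Base class for all drnaprof errors."""


class InvalidParameterError(DrnaprofError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(DrnaprofError, ValueError):
    """An input file does not parse as the expected format."""


class AlphabetError(DrnaprofError, ValueError):
    """A sequence contains characters outside the supported alphabet."""


class UnsupportedCigarError(DrnaprofError, ValueError):
    """A CIGAR cannot be resolved (M without reference, or P/B ops)."""


class EmptyInputError(DrnaprofError, ValueError):
    """An operation received no usable input."""


class SegmentationError(DrnaprofError, ValueError):
    """Move table and basecall length disagree."""


class InsufficientDataError(DrnaprofError, ValueError):
    """Too few observations for a meaningful statistic."""


class DegenerateFitError(DrnaprofError, ValueError):
    """A regression cannot be fitted (constant predictor or n too small)."""


class ConfigurationError(DrnaprofError, ValueError):
    """Pipeline configuration is invalid or references missing inputs."""


class InternalConsistencyError(DrnaprofError, RuntimeError):
    """Inputs that should agree by construction do not."""
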