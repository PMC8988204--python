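"""Exception hierarchy used across the pipeline.

All domain errors derive from :class:`CanopynetError` so callers can catch
one base class; most also derive from the closest builtin (``ValueError``,
``IOError``) so idiomatic handling keeps working.
"""


class CanopynetError(Exception):
    """Base class for all canopynet errors."""


class InvalidArgumentError(CanopynetError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(CanopynetError, ValueError):
    """A model/training/run configuration is internally inconsistent."""


class ShapeError(CanopynetError, ValueError):
    """An array has the wrong shape for the requested operation."""


class EmptyInputError(CanopynetError, ValueError):
    """An operation that needs data received an empty container."""


class InsufficientDataError(CanopynetError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateRangeError(CanopynetError, ValueError):
    """A denominator (range, variance, mean) is zero where it must not be."""


class PointCloudFormatError(CanopynetError, ValueError):
    """A point-cloud file does not follow the expected schema."""


class PointCloudValidationError(CanopynetError, ValueError):
    """Point-cloud values are out of their physical/normalized range."""


class DivergenceError(CanopynetError, RuntimeError):
    """Training produced a non-finite loss.

    Attributes
    ----------
    epoch : int
        Zero-based epoch index at which the divergence was detected.
    """

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch
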