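"""Exception hierarchy for the measurement pipeline.

Each leaf maps to a distinct CLI exit code (see :mod:`fishlength.cli`).
"""


class FishLengthError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FishLengthError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(FishLengthError, RuntimeError):
    """An object is not in the state an operation requires."""


class ConfigError(FishLengthError):
    """The measurement configuration is missing fields or inconsistent."""


class InputError(FishLengthError):
    """An input image pair is unreadable or mismatched."""


class NoFishError(FishLengthError):
    """The segmentation mask contains no usable fish region."""


class MissingDepthError(FishLengthError):
    """No valid depth reading near a measurement point."""


class RefractionNotApplicableError(InvalidArgumentError):
    """A point lies above the water surface, so no correction applies."""


class ProjectionFailureError(FishLengthError):
    """The forward ray tracer could not bracket a surface crossing."""
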