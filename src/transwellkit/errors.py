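"""Exception and warning types shared across the package.

The two error classes map onto the CLI exit-code contract:
``InputValidationError`` → exit 2 (malformed or inconsistent input),
``DegenerateInputError`` → exit 3 (input that is well-formed but cannot
support the requested estimate, e.g. a flat calibration line).
"""


class TranswellError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputValidationError(TranswellError):
    """Input violates a schema or cross-record consistency requirement."""

    exit_code = 2


class DegenerateInputError(TranswellError):
    """Input is structurally valid but the estimate is undefined on it."""

    exit_code = 3


class OutOfRangeWarning(UserWarning):
    """A back-calculated concentration falls outside the validated range."""


class MissingTeerWarning(UserWarning):
    """A transport series carries no TEER reading; the gate passes it."""
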