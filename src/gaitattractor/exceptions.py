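"""Exception hierarchy.

Exit-code mapping in the CLI relies on the three branches below:
configuration (bad parameters), parsing (bad input files), and
computation (a stage of the analysis failed on valid-looking input).
"""


class GaitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitError):
    """Invalid parameter or configuration value."""


class ParseError(GaitError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(GaitError):
    """Structurally valid input that violates a domain invariant."""


class ComputationError(GaitError):
    """An analysis stage failed (too few strides, detection failure, ...)."""


class DetectionError(ComputationError):
    """Heel-strike detection found no usable periodicity."""


class WindowError(ComputationError):
    """The beginning/end walk windows cannot be placed (recording too short)."""
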