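"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`UnbindmlError`, so callers can catch the package's failures without
swallowing genuine bugs.
"""


class UnbindmlError(Exception):
    """Base class for all errors raised by unbindml."""


class ParseError(UnbindmlError):
    """A structure or restraint file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(UnbindmlError):
    """Invalid user-supplied configuration or selection."""


class StructuralError(UnbindmlError):
    """Topology and data disagree (atom counts, feature counts, ...)."""


class GeometryError(UnbindmlError):
    """Degenerate geometry (too few atoms, collinear selection, ...)."""


class ProtocolError(UnbindmlError):
    """The iterative unbinding protocol cannot continue."""


class GenerationError(UnbindmlError):
    """A synthetic-data generator could not produce a valid ensemble."""


class TrainingError(UnbindmlError):
    """Classifier-ensemble training preconditions violated."""


class SelectionError(UnbindmlError):
    """No valid candidate to select (e.g. no decided downhill shots)."""
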