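"""Exception hierarchy shared across the engine."""


class CogRehabError(Exception):
    """Base class for all errors raised by cogrehab."""


class ParseError(CogRehabError):
    """Syntax error in a profile-language sentence.

    Carries the 0-based character position of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownLabelError(CogRehabError):
    """A sentence or term references a label absent from the schema."""

    def __init__(self, label: str):
        super().__init__(f"unknown label: {label!r}")
        self.label = label


class SchemaError(CogRehabError):
    """Invalid schema definition, off-grid value, or schema mismatch."""


class StateSpaceError(CogRehabError):
    """Model enumeration would exceed the configured state-space cap."""

    def __init__(self, size: int, cap: int):
        super().__init__(
            f"state space of {size} grid profiles exceeds the cap of {cap}"
        )
        self.size = size
        self.cap = cap


class InconsistencyError(CogRehabError):
    """A revision sentence has no model on the schema grid."""


class NoCandidateError(CogRehabError):
    """Task filtering left no candidate training task."""


class DataValidationError(CogRehabError):
    """An input document failed structural validation."""
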