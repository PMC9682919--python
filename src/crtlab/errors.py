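"""Exception hierarchy for crtlab."""


class CrtError(Exception):
    """Base class for all crtlab errors."""


class ValidationError(CrtError, ValueError):
    """A domain object violates one of its invariants."""


class SequenceGenerationError(CrtError):
    """Constrained stimulus-sequence generation exhausted its retry budget."""


class FitError(CrtError):
    """The RevEx fit cannot be performed on the given sample."""


class ParseError(CrtError):
    """A session or score file violates its schema.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
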