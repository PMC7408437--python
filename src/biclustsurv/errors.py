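"""Exception hierarchy shared across the package."""


class BiclustSurvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiclustSurvError, ValueError):
    """A specification or configuration field violates its invariant."""


class DegenerateInputError(BiclustSurvError, ValueError):
    """Input is too small or too degenerate for the requested statistic."""


class ParseError(BiclustSurvError, ValueError):
    """A table file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
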