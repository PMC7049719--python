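"""Exception hierarchy for the package."""


class InsertionFateError(Exception):
    """Base class for package errors."""


class ValidationError(InsertionFateError):
    """An input violates a documented invariant."""


class ParseError(InsertionFateError):
    """A file could not be parsed; names the offending line."""

    def __init__(self, path, line_no, message):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class InsufficientDataError(InsertionFateError):
    """Too few observations to compute the requested statistic."""
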