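"""Exception hierarchy shared by all polyassoc modules."""


class PolyassocError(Exception):
    """Base class for all package errors."""


class ParseError(PolyassocError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PolyassocError):
    """Input violates a documented invariant (bad genotype, duplicate id, ...)."""


class ConfigurationError(PolyassocError):
    """A required configuration step has not been performed."""


class SeparationError(PolyassocError):
    """Perfect separation detected during logistic regression."""


class ConvergenceError(PolyassocError):
    """IRLS failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = list(trace or [])
        super().__init__(message)
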