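"""Exception hierarchy."""


class ChromascopeError(Exception):
    """Base class for package-specific errors."""


class ParseError(ChromascopeError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConvergenceError(ChromascopeError, RuntimeError):
    """Iterative procedure failed to reach its tolerance."""


class DegenerateInputError(ChromascopeError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-zero map)."""
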