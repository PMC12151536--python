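"""Exception types shared across the package."""


class RegmapError(Exception):
    """Base class for all package errors."""


class ValidationError(RegmapError):
    """Raised when an input value violates a documented precondition."""


class ParseError(RegmapError):
    """Raised when a text input file cannot be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)
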