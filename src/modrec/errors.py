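"""Exception types shared across the package."""


class ModrecError(Exception):
    """Base class for all package-specific errors."""


class EdgeListParseError(ModrecError, ValueError):
    """A line of an edge-list file could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ValidationError(ModrecError, ValueError):
    """An input violates a documented precondition."""
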