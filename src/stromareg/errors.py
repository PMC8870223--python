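class StromaregError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(StromaregError):
    """Malformed input file; carries file path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DegenerateDataError(StromaregError):
    """Input carries no information for the requested analysis (e.g. zero events)."""
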