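"""Exception hierarchy shared across the toolkit."""


class DynamethError(Exception):
    """Base class for all data / validation errors raised by dynameth."""


class ParseError(DynamethError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


class ValidationError(DynamethError):
    """An input violated an invariant (counts, coordinates, ranges)."""
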