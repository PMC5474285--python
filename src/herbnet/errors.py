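"""Exception hierarchy shared across the pipeline."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class ParseError(HerbnetError):
    """A file could not be parsed.

    Carries enough context (row/line and column where applicable) to point
    the user at the offending cell.
    """

    def __init__(self, message: str, *, row: int | None = None,
                 column: str | None = None, line: int | None = None):
        self.row = row
        self.column = column
        self.line = line
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class ValidationError(HerbnetError):
    """Input violated a domain invariant (e.g. negative expression value)."""


class StageError(HerbnetError):
    """A pipeline stage failed; names the stage and the underlying cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
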