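"""Exception hierarchy.

``DataValidationError`` covers malformed or inconsistent inputs (exit code 2
on the command line); ``ComputationError`` covers failures arising during an
otherwise well-posed calculation (exit code 3).
"""


class LariskError(Exception):
    """Base class for all package errors."""


class DataValidationError(LariskError, ValueError):
    """An input table, config or parameter violated its contract."""


class TableFormatError(DataValidationError):
    """A file failed to parse; carries file, line and column context."""

    def __init__(self, message: str, *, path: str | None = None,
                 line: int | None = None, column: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = f"[{', '.join(loc)}] " if loc else ""
        super().__init__(prefix + message)
        self.path = path
        self.line = line
        self.column = column


class ComputationError(LariskError, RuntimeError):
    """A well-formed request could not be computed (e.g. extinct cohort)."""
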