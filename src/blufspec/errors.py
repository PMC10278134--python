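"""Exception hierarchy shared by all stages.

The CLI maps these onto process exit codes: validation errors exit 2,
parse errors 3, numerical failures 4.
"""

from __future__ import annotations


class BlufspecError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(BlufspecError):
    """Invalid input values, shapes or configuration."""

    exit_code = 2


class SelectionError(ValidationError):
    """An atom/residue selector did not resolve uniquely."""


class DegenerateGeometryError(ValidationError):
    """Geometry degenerate for the requested metric (zero vector, collinear)."""


class ParseError(BlufspecError):
    """Malformed input file."""

    exit_code = 3

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class NumericalError(BlufspecError):
    """A numerical procedure failed to reach its accuracy contract."""

    exit_code = 4


class TruncationError(NumericalError):
    """An energy/time grid was too narrow for the requested quantity."""


class AlignmentError(NumericalError):
    """No usable first maximum was found for spectral alignment."""
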