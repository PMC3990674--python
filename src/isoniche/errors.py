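"""Exception hierarchy shared across the package."""

from __future__ import annotations


class IsonicheError(Exception):
    """Base class for all package errors."""


class InvalidInputError(IsonicheError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(IsonicheError):
    """A tabular input is missing required columns or categories."""


class RowError(IsonicheError):
    """One or more rows of a tabular input could not be parsed.

    Attributes
    ----------
    bad_cells : list of (line_number, column, raw_value)
    """

    def __init__(self, message: str, bad_cells: list[tuple[int, str, str]]):
        super().__init__(message)
        self.bad_cells = bad_cells


class DegenerateGeometryError(InvalidInputError):
    """Point configuration is too degenerate for the requested geometry."""


class ConvergenceError(IsonicheError):
    """An iterative fit failed to converge.

    For MCMC fits, ``rhat`` holds the per-parameter split-R-hat table that
    triggered the failure.
    """

    def __init__(self, message: str, rhat=None, gradient_norm=None):
        super().__init__(message)
        self.rhat = rhat
        self.gradient_norm = gradient_norm
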