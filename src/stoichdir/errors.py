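"""Exception hierarchy for stoichdir."""

from __future__ import annotations


class StoichdirError(Exception):
    """Base class for all stoichdir errors."""


class MatrixFormatError(StoichdirError):
    """The input table is structurally unusable (empty, ragged, missing ids)."""


class MatrixParseError(StoichdirError):
    """A cell of the input table is not an integer.

    Carries the offending row and column labels so the user can fix the file.
    """

    def __init__(self, message: str, row: str | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class NetworkValidationError(StoichdirError):
    """The stoichiometry matrix violates a hard structural constraint.

    The full :class:`~stoichdir.network_model.ValidationReport` is attached
    as ``report``.
    """

    def __init__(self, report):
        super().__init__("stoichiometry matrix failed validation: " + ", ".join(report.failures))
        self.report = report


class NullityError(StoichdirError):
    """The null space is too small for directionality inference (nullity < 2)."""


class GenerationError(StoichdirError):
    """The synthetic-network generator could not satisfy its constraints."""
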