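"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`ddspls.cli`).
"""


class DdsplsError(Exception):
    """Base class for all package errors."""


class SchemaError(DdsplsError):
    """Structural problem with input data (columns, shapes, names)."""


class AlignmentError(SchemaError):
    """Row identifiers cannot be matched across files."""


class MissingDataError(SchemaError):
    """Input contains empty cells; v1 does not impute."""


class ParameterError(DdsplsError):
    """Invalid algorithm parameter (negative lambda, R > q, ...)."""


class DegenerateInputError(DdsplsError):
    """Input is valid in shape but statistically degenerate."""


class NoSignalError(DdsplsError):
    """Every cross-covariance entry is zero; nothing can be selected."""
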