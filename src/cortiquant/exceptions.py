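"""Exception hierarchy.

Every error a pipeline stage can raise derives from :class:`CortiquantError`
so the CLI can convert any stage failure into a one-line diagnostic and a
nonzero exit status.
"""


class CortiquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CortiquantError):
    """Invalid generator/analysis configuration (bad spacing, rate, key...)."""


class DomainError(CortiquantError):
    """A value outside the domain an operation is defined on."""


class InsufficientDataError(CortiquantError):
    """Too few cells/samples to run the requested computation."""


class InsufficientNeighborsError(InsufficientDataError):
    """A focal cell has fewer candidate neighbors than requested."""


class DegenerateGeometryError(CortiquantError):
    """Coincident points or otherwise degenerate geometry in the input."""


class DegenerateDesignError(CortiquantError):
    """A statistical design with no usable within-group variance."""


class SchemaError(CortiquantError):
    """A table is missing required columns or has a malformed header."""


class ParseError(CortiquantError):
    """A table cell failed to parse; carries a line number when known."""


class IntegrityError(CortiquantError):
    """Duplicate identifiers or other referential problems in a table."""
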