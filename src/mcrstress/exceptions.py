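"""Exception hierarchy shared across the package.

All errors derive from :class:`McrError` so callers (and the CLI) can map
them onto exit codes: schema problems, configuration problems and
computation problems are distinguished.
"""


class McrError(Exception):
    """Base class for all package errors."""


class DomainError(McrError, ValueError):
    """An argument is outside its documented domain (bad ordinal, bad count)."""


class ConfigError(McrError, ValueError):
    """A configuration object failed validation.

    ``fields`` lists the offending field names when known.
    """

    def __init__(self, message, fields=()):
        super().__init__(message)
        self.fields = tuple(fields)


class SchemaError(McrError, ValueError):
    """A table is missing required columns or contains ill-typed values."""


class CoverageError(McrError, ValueError):
    """A performance plane has uncovered difficulty cells.

    ``cells`` holds the (motor, cognitive) ordinals that could not be scored.
    """

    def __init__(self, message, cells=()):
        super().__init__(message)
        self.cells = tuple(cells)


class ComputationError(McrError, RuntimeError):
    """A numerical stage failed (degenerate input, rank deficiency, ...)."""
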