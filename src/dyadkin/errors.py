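"""Exception hierarchy.

All dyadkin-specific failures derive from :class:`DyadkinError` so callers
can catch one base class; the CLI maps ``ValidationError`` to exit code 2
and ``ParseError``/OS errors to exit code 3.
"""


class DyadkinError(Exception):
    """Base class for all dyadkin errors."""


class ValidationError(DyadkinError, ValueError):
    """Input violates a documented invariant or precondition."""


class ParseError(DyadkinError, ValueError):
    """A file could not be parsed against its documented schema."""


class DegenerateGeometryError(ValidationError):
    """Point correspondences too degenerate for a rigid-transform fit."""
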