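"""Exception types shared across the package."""


class NanospringError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NanospringError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DegenerateGeometryError(NanospringError, ValueError):
    """Geometry too degenerate to fit (collinear points, zero-length trace, ...)."""


class ParseError(NanospringError, ValueError):
    """Malformed input file."""
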