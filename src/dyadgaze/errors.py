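"""Exception hierarchy shared across the package."""


class DyadGazeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DyadGazeError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class SchemaError(DyadGazeError):
    """A delimited table does not conform to its declared schema.

    Carries the offending field and, where known, the 1-based line number.
    """

    def __init__(self, message: str, field: str | None = None,
                 line: int | None = None):
        self.field = field
        self.line = line
        where = []
        if field is not None:
            where.append(f"field {field!r}")
        if line is not None:
            where.append(f"line {line}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class AnnotationError(DyadGazeError):
    """Speech annotation events are malformed (bad nesting or ordering)."""


class InsufficientDataError(DyadGazeError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(DyadGazeError):
    """Data admits no informative statistic (e.g. all-zero differences)."""
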