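"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class MissingDataError(ValidationError):
    """A required field is absent in strict mode."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"required field {field!r} is missing")


class SchemaError(ValidationError):
    """A tabular input file does not match the documented schema.

    ``rows`` holds (line_number, message) pairs for every offending row.
    """

    def __init__(self, message: str, rows: list[tuple[int, str]] | None = None):
        self.rows = rows or []
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.rows)
        super().__init__(message + (f" [{detail}]" if detail else ""))


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge (e.g. complete separation)."""


class DegenerateInputError(ValidationError):
    """Input is valid but makes the requested statistic undefined."""
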