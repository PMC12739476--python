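"""Exception hierarchy shared by all pipeline stages."""


class DroughtEvalError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(DroughtEvalError):
    """An input table is missing a required column or uses an unknown layout."""


class TableParseError(DroughtEvalError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class IntegrityError(DroughtEvalError):
    """Duplicate keys, unknown codes, or non-finite values in a validated table."""


class CompletenessError(DroughtEvalError):
    """A genotype x stage x indicator cell has no replicate measurements."""

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(map(str, self.missing[:5]))
        more = "" if len(self.missing) <= 5 else f" (+{len(self.missing) - 5} more)"
        super().__init__(f"missing cells: {preview}{more}")


class DegenerateDataError(DroughtEvalError):
    """A computation hit a degenerate input (constant column, zero denominator)."""


class EvaluationError(DroughtEvalError):
    """Dimension mismatches or invalid configuration in the evaluation stage."""
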