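"""Package exception hierarchy."""


class KirPatternsError(Exception):
    """Base class for all kirpatterns errors."""


class SchemaError(KirPatternsError):
    """An input table is missing a required column or is malformed."""


class ParseError(KirPatternsError):
    """A cell value could not be interpreted as binary presence/absence."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateSelectionError(KirPatternsError):
    """A frequency or statistic was requested over an empty selection."""


class SingleClassError(KirPatternsError):
    """An operation requiring both classes was given a one-class cohort."""


class InfeasibleSpecError(KirPatternsError):
    """A synthetic-cohort specification is internally inconsistent."""
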