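"""Exception hierarchy shared across the package."""


class CnvBurdenError(Exception):
    """Base class for all package errors."""


class SchemaError(CnvBurdenError):
    """A tabular input is missing required columns or has the wrong header."""


class ValidationError(CnvBurdenError):
    """Rows violate a record invariant (e.g. start >= end); carries row numbers."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ConfigError(CnvBurdenError):
    """A configuration value is out of range or references unknown terms."""


class SizingError(CnvBurdenError):
    """A simulated layout cannot fit (total gene span exceeds the genome)."""


class MatchingError(CnvBurdenError):
    """A case CNV has no admissible match in the resampling pool."""

    def __init__(self, message: str, unmatched: list | None = None):
        super().__init__(message)
        self.unmatched = unmatched or []


class SeparationError(CnvBurdenError):
    """Complete separation under a flat prior; a weakly-informative prior is advised."""


class DiagnosticError(CnvBurdenError):
    """A resampling run failed its internal quality checks (e.g. too many failed refits)."""


class InsufficientDataError(CnvBurdenError):
    """Too few observations to compute the requested statistic."""
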