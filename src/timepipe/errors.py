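"""Exception hierarchy for the pipeline."""


class TimepipeError(Exception):
    """Base class for all package errors."""


class SchemaError(TimepipeError):
    """A required column is missing or mis-typed."""


class ValidationError(TimepipeError):
    """Row-level invariant violations; carries row-indexed diagnostics."""

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        super().__init__(message)


class ReferentialError(TimepipeError):
    """A foreign key (e.g. patient_id) has no match in the reference table."""


class ParameterError(TimepipeError):
    """An operation was called with an out-of-range or unknown parameter."""


class DegenerateSpecError(TimepipeError):
    """A cohort spec that cannot produce a meaningful simulation."""


class StratificationError(TimepipeError):
    """Too few examples of a class to split into train/test."""


class CalibrationError(TimepipeError):
    """Gating cannot be calibrated (e.g. no annotated negatives)."""


class DegenerateDistributionError(TimepipeError):
    """A marker distribution with no variance cannot be gated."""


class DependencyError(TimepipeError):
    """A stage was invoked before a stage it depends on."""


class CohortError(TimepipeError):
    """A comparison group is empty or otherwise unusable."""
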