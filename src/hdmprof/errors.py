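"""Exception hierarchy for cohort ingest and analysis."""


class HdmprofError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HdmprofError):
    """The input table is missing a required column or has a malformed header."""


class RowError(HdmprofError):
    """A single patient row violates a value constraint.

    Carries the offending patient_id and column so the row can be located
    in the source file.
    """

    def __init__(self, patient_id: str, column: str, message: str):
        self.patient_id = patient_id
        self.column = column
        super().__init__(f"patient {patient_id!r}, column {column!r}: {message}")


class DuplicateIDError(HdmprofError):
    """Two rows share the same patient_id."""


class UndefinedDenominatorError(HdmprofError):
    """A percentage was requested for an empty group."""


class ConsistencyError(HdmprofError):
    """Internal invariant violated (e.g. all-zero shares with sensitized patients)."""


class ConfigError(HdmprofError):
    """An analysis or simulation configuration value is out of range."""
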