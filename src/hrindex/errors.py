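"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`HrindexError`, so
callers (and the CLI) can catch one base class. Subclasses mirror the
failure modes of the pipeline stages: schema problems on ingest, row-level
invariant violations, empty selections, domain errors on model inputs, and
degenerate statistical designs.
"""

from __future__ import annotations


class HrindexError(Exception):
    """Base class for all errors raised by hrindex."""


class SchemaError(HrindexError):
    """A delimited table is missing a required column or has a bad header."""


class RecordValidationError(HrindexError):
    """A row violates a StudyRecord invariant.

    Carries the offending ``study_id`` and ``field`` so batch ingest can
    point at the exact cell.
    """

    def __init__(self, message: str, *, study_id: str | None = None,
                 field: str | None = None) -> None:
        super().__init__(message)
        self.study_id = study_id
        self.field = field


class EmptySelectionError(HrindexError):
    """A summary was requested over an empty collection of records."""


class DomainError(HrindexError, ValueError):
    """A model input lies outside the domain the model is defined on."""


class MissingDataError(HrindexError):
    """A record lacks a field an operation requires; names the field."""

    def __init__(self, message: str, *, study_id: str | None = None,
                 field: str | None = None) -> None:
        super().__init__(message)
        self.study_id = study_id
        self.field = field


class PairingError(HrindexError):
    """Paired samples have unequal lengths."""


class InsufficientDataError(HrindexError):
    """Too few observations for the requested statistic."""


class RegistryError(HrindexError, KeyError):
    """An equation name is not present in the registry."""


class DegenerateDesignError(HrindexError):
    """A regression design is degenerate (e.g. zero predictor variance)."""


class ConfigError(HrindexError):
    """A synthetic-cohort configuration field is invalid; names the field."""

    def __init__(self, message: str, *, field: str | None = None) -> None:
        super().__init__(message)
        self.field = field
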