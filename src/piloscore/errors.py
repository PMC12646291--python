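"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PiloscoreError(Exception):
    """Base class for all package errors."""


class ConfigError(PiloscoreError):
    """A weight table or simulation spec is malformed or does not cover a value."""


class RecordValidationError(PiloscoreError):
    """A patient record violates its invariants.

    Carries the list of :class:`~piloscore.records.Violation` objects so
    callers can report every offending field at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"{v.field}: {v.rule}" for v in self.violations)
        super().__init__(f"invalid patient record ({msg})")


class DegenerateDataError(PiloscoreError):
    """The data admit no meaningful statistic (zero margin, zero variance...)."""
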