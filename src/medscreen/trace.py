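"""Traceability records.

Every evaluation keeps an ordered activity log: which rules fired, which
alerts were emitted or suppressed, and every knowledge gap encountered
(unmapped local codes, missing weights, impossible unit conversions,
absent laboratory values).  The log is the audit trail reviewers use to
see what the engine silently skipped.
"""

from __future__ import annotations

import datetime as _dt

from pydantic import BaseModel, Field


class TraceRecord(BaseModel):
    at: _dt.datetime = Field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc))
    patient_id: str = ""
    rule: str = ""
    outcome: str = ""
    detail: dict = Field(default_factory=dict)


class Trace(list):
    """Ordered collection of :class:`TraceRecord`, with a convenience
    :meth:`add`. Passing a ``Trace`` to a scoring function switches it
    from raise-on-gap to record-and-continue behaviour."""

    def __init__(self, patient_id: str = ""):
        super().__init__()
        self.patient_id = patient_id

    def add(self, rule: str, outcome: str, **detail) -> TraceRecord:
        rec = TraceRecord(patient_id=self.patient_id, rule=rule, outcome=outcome, detail=detail)
        self.append(rec)
        return rec
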