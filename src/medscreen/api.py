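"""JSON request/response facade.

:func:`handle_request` is the function an integration layer (a CPOE
hook, a message queue worker, a web framework route) would call once per
prescribing event: JSON in, a structured, schema-valid response out,
never an exception. The response carries the three scores, the display
records of the emitted alerts (generic drug names, or "Review total
treatment" for regimen-level interventions), the suppressed alert ids
and the full trace.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field

from . import __version__ as _engine_version
from .alerts import Alert, EvaluationResult, SuppressionRegistry, evaluate
from .errors import CaseValidationError
from .kb import KnowledgeBase
from .patient import parse_case
from .trace import TraceRecord


class AlertDisplay(BaseModel):
    """What the prescriber sees for one alert."""

    alert_id: str
    use_case: str
    text: str  # generic drug name(s), or "Review total treatment"
    description: str
    recommendation: str
    color: str
    level: str
    link: str = ""


class ScoreBlock(BaseModel):
    mrci_section_a: float = 0.0
    mrci_section_b: float = 0.0
    mrci_section_c: float = 0.0
    mrci_total: float = 0.0
    dbi_total: float = 0.0
    dbi_terms: list[dict] = Field(default_factory=list)
    trigger_hits: list[dict] = Field(default_factory=list)


class EvaluationResponse(BaseModel):
    """Top-level JSON response; ``status`` is "ok" for any completed
    evaluation (even a partial one with trace annotations) and
    "invalid_request" when the document never parsed."""

    status: Literal["ok", "invalid_request"]
    patient_id: str = ""
    eligible: bool = False
    scores: ScoreBlock = Field(default_factory=ScoreBlock)
    alerts: list[AlertDisplay] = Field(default_factory=list)
    suppressed: list[str] = Field(default_factory=list)
    errors: list[dict] = Field(default_factory=list)
    trace: list[TraceRecord] = Field(default_factory=list)
    engine_version: str = _engine_version
    kb_version: str = ""


def display(alert: Alert) -> AlertDisplay:
    """Render an alert for display: specific-drug interventions show the
    generic drug name(s); global ones show "Review total treatment"."""
    text = ", ".join(t.label for t in alert.targets)
    return AlertDisplay(
        alert_id=alert.alert_id,
        use_case=alert.use_case,
        text=text,
        description=alert.template.description,
        recommendation=alert.template.recommendation,
        color=alert.display_color,
        level=alert.template.level,
        link=alert.template.link,
    )


def response_from_result(result: EvaluationResult, kb: KnowledgeBase) -> EvaluationResponse:
    return EvaluationResponse(
        status="ok",
        patient_id=result.patient_id,
        eligible=result.eligible,
        scores=ScoreBlock(
            mrci_section_a=result.mrci.section_a,
            mrci_section_b=result.mrci.section_b,
            mrci_section_c=result.mrci.section_c,
            mrci_total=result.mrci.total,
            dbi_total=result.dbi.total,
            dbi_terms=[{"order_id": t.order_id, "ingredient": t.ingredient.label,
                        "daily_dose": t.daily_dose, "delta": t.delta, "term": t.term}
                       for t in result.dbi.terms],
            trigger_hits=[{"order_id": h.order_id, "lab_test": h.entry.lab_test.label,
                           "value": h.observed_value, "unit": h.observed_unit,
                           "direction": h.direction,
                           "range": [h.entry.low, h.entry.high]}
                          for h in result.trigger_hits],
        ),
        alerts=[display(a) for a in result.alerts],
        suppressed=list(result.suppressed),
        trace=result.trace,
        kb_version=kb.version,
    )


def handle_request(document: str | bytes | dict, kb: KnowledgeBase,
                   registry: SuppressionRegistry | None = None,
                   include_prn: bool = False) -> EvaluationResponse:
    """Parse, evaluate and respond; malformed input yields a structured
    error response rather than an exception."""
    from .trace import Trace

    parse_trace = Trace()
    try:
        case = parse_case(document, kb, trace=parse_trace)
    except CaseValidationError as exc:
        return EvaluationResponse(status="invalid_request", errors=exc.errors,
                                  kb_version=kb.version)
    result = evaluate(case, kb, registry, include_prn)
    response = response_from_result(result, kb)
    # mapping gaps found at parse time belong in the same audit trail
    response.trace = list(parse_trace) + response.trace
    return response
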