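"""Alerting rules, soft-stop suppression, and evaluation orchestration.

The engine screens only patients at or above the minimum age (65 by
default). For eligible patients it raises

* one regimen-complexity alert when the MRCI total reaches the cut-off
  (40 by default) — a *global drug* intervention displayed as
  "Review total treatment",
* one drug-burden alert when the DBI total reaches its cut-off (1.0 by
  default), listing every contributing drug, and
* one alert per fired laboratory trigger, naming the drug.

Alerts are soft stops: the clinician may accept or ignore each one, and
an alert ignored once is never shown again for that patient (the
ignore-once rule, an alert-fatigue countermeasure). Alert identifiers
are deterministic so suppression survives re-evaluation. Display colors
encode clinical relevance: red (contraindicated), orange (moderate),
yellow (low), blue (risk minimization).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field

from .dbi import DBIScore, score_dbi
from .errors import DomainError
from .kb import AlertTemplate, ConceptRef, KnowledgeBase
from .mrci import MRCIScore, score_mrci
from .patient import PatientCase
from .trace import Trace, TraceRecord
from .triggers import TriggerHit, screen_triggers

UseCase = Literal["mrci", "dbi", "trigger"]
Color = Literal["red", "orange", "yellow", "blue"]

#: Sentinel target for global-drug interventions.
REVIEW_TOTAL_TREATMENT = ConceptRef(id="medscreen:review-total-treatment",
                                    label="Review total treatment")

_COLORS: dict[str, Color] = {
    "contraindicated": "red",
    "moderate": "orange",
    "low": "yellow",
    "risk_minimization": "blue",
}


def color_for(level: str) -> Color:
    """Display color for a clinical-relevance level."""
    try:
        return _COLORS[level]
    except KeyError:
        raise DomainError(f"unknown alert level {level!r}") from None


class Alert(BaseModel):
    """One decision-support message."""

    alert_id: str
    use_case: UseCase
    template: AlertTemplate
    targets: list[ConceptRef]
    display_color: Color
    payload: dict = Field(default_factory=dict)


def _alert_id(use_case: str, template_id: str, target_ids: list[str]) -> str:
    key = "|".join([use_case, template_id] + sorted(target_ids))
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def make_alert(use_case: UseCase, template: AlertTemplate,
               targets: list[ConceptRef], payload: dict | None = None) -> Alert:
    """Construct an alert with its deterministic id and level-derived color.

    Global-drug interventions always target the whole regimen (the
    sentinel "Review total treatment" concept).
    """
    if template.intervention == "global_drug":
        targets = [REVIEW_TOTAL_TREATMENT]
    if use_case == "mrci" and template.intervention != "global_drug":
        raise DomainError("regimen-complexity alerts require a global_drug template")
    return Alert(
        alert_id=_alert_id(use_case, template.id, [t.id for t in targets]),
        use_case=use_case,
        template=template,
        targets=targets,
        display_color=color_for(template.level),
        payload=payload or {},
    )


class SuppressionRegistry(BaseModel):
    """Per-patient soft-stop state, persistable as a JSON file.

    ``ignored`` holds (patient, alert) pairs with the timestamp of the
    ignore — set semantics, so repeated ignores are idempotent.
    ``emitted`` remembers which alert ids each patient has been shown,
    which is what makes responses verifiable. ``responses`` is the
    append-only log of clinician actions.
    """

    ignored: dict[str, dict[str, str]] = Field(default_factory=dict)
    emitted: dict[str, list[str]] = Field(default_factory=dict)
    responses: list[dict] = Field(default_factory=list)

    def is_suppressed(self, patient_id: str, alert_id: str) -> bool:
        return alert_id in self.ignored.get(patient_id, {})

    def note_emitted(self, patient_id: str, alert_ids: list[str]) -> None:
        known = self.emitted.setdefault(patient_id, [])
        for aid in alert_ids:
            if aid not in known:
                known.append(aid)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SuppressionRegistry":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))


def record_response(registry: SuppressionRegistry, patient_id: str, alert_id: str,
                    action: Literal["accepted", "ignored"]) -> SuppressionRegistry:
    """Record a clinician's decision on an emitted alert.

    Only "ignored" suppresses future displays; "accepted" is logged but
    the alert reappears while its condition persists. Responding to an
    alert never emitted for that patient is a domain error.
    """
    if alert_id not in registry.emitted.get(patient_id, []):
        raise DomainError(f"alert {alert_id!r} was never emitted for patient {patient_id!r}")
    if action not in ("accepted", "ignored"):
        raise DomainError(f"unknown action {action!r}")
    now = _dt.datetime.now(_dt.timezone.utc).isoformat()
    registry.responses.append(
        {"patient_id": patient_id, "alert_id": alert_id, "action": action, "at": now})
    if action == "ignored":
        registry.ignored.setdefault(patient_id, {}).setdefault(alert_id, now)
    return registry


class EvaluationResult(BaseModel):
    """Everything one evaluation produced: the three scores, the emitted
    and suppressed alerts, and the full activity trace."""

    patient_id: str
    eligible: bool
    mrci: MRCIScore
    dbi: DBIScore
    trigger_hits: list[TriggerHit]
    alerts: list[Alert]
    suppressed: list[str]
    trace: list[TraceRecord]


def is_eligible(case: PatientCase, kb: KnowledgeBase) -> bool:
    """Screening applies from the KB's minimum age upward (default 65)."""
    return case.age_years >= kb.thresholds.min_age_years


def evaluate(case: PatientCase, kb: KnowledgeBase,
             registry: SuppressionRegistry | None = None,
             include_prn: bool = False) -> EvaluationResult:
    """Score the case, apply the alerting rules, and filter soft-stopped
    alerts.

    Scores are always computed and traced; alerts are raised only for
    eligible patients. Knowledge gaps (missing weights, failed unit
    conversions, unmapped concepts) become trace records, never
    exceptions — a partial evaluation with an audit trail beats none.
    """
    trace = Trace(case.patient_id)
    mrci = score_mrci(case, kb, include_prn, trace=trace)
    dbi = score_dbi(case, kb, include_prn, trace=trace)
    hits = screen_triggers(case, kb, include_prn, trace=trace)
    trace.add("scores", "computed", mrci_total=mrci.total, dbi_total=dbi.total,
              trigger_hits=len(hits))

    eligible = is_eligible(case, kb)
    trace.add("eligibility", "eligible" if eligible else "ineligible",
              age_years=case.age_years, min_age_years=kb.thresholds.min_age_years)

    candidates: list[Alert] = []
    if eligible:
        if mrci.total >= kb.thresholds.mrci_alert:
            template = kb.template(kb.mrci_template_id)
            if template is None:
                trace.add("alerts.mrci", "no_template", template_id=kb.mrci_template_id)
            else:
                candidates.append(make_alert(
                    "mrci", template, [REVIEW_TOTAL_TREATMENT],
                    payload={"mrci_total": mrci.total,
                             "sections": {"a": mrci.section_a, "b": mrci.section_b,
                                          "c": mrci.section_c},
                             "threshold": kb.thresholds.mrci_alert}))
        if dbi.total >= kb.thresholds.dbi_alert:
            template = kb.template(kb.dbi_template_id)
            if template is None:
                trace.add("alerts.dbi", "no_template", template_id=kb.dbi_template_id)
            else:
                drugs: dict[str, ConceptRef] = {t.ingredient.id: t.ingredient for t in dbi.terms}
                candidates.append(make_alert(
                    "dbi", template, list(drugs.values()),
                    payload={"dbi_total": dbi.total,
                             "terms": [{"ingredient": t.ingredient.id, "term": t.term}
                                       for t in dbi.terms],
                             "threshold": kb.thresholds.dbi_alert}))
        for hit in hits:
            template = kb.template(hit.entry.alert_template_id)
            if template is None:
                trace.add("alerts.trigger", "no_template",
                          template_id=hit.entry.alert_template_id)
                continue
            candidates.append(make_alert(
                "trigger", template, [hit.entry.ingredient],
                payload={"lab_test": hit.entry.lab_test.id,
                         "observed_value": hit.observed_value,
                         "observed_unit": hit.observed_unit,
                         "direction": hit.direction,
                         "range": [hit.entry.low, hit.entry.high]}))

    alerts: list[Alert] = []
    suppressed: list[str] = []
    for alert in candidates:
        if registry is not None and registry.is_suppressed(case.patient_id, alert.alert_id):
            suppressed.append(alert.alert_id)
            trace.add(f"alerts.{alert.use_case}", "suppressed", alert_id=alert.alert_id)
        else:
            alerts.append(alert)
            trace.add(f"alerts.{alert.use_case}", "emitted", alert_id=alert.alert_id,
                      targets=[t.id for t in alert.targets])
    if registry is not None:
        registry.note_emitted(case.patient_id, [a.alert_id for a in candidates])

    return EvaluationResult(patient_id=case.patient_id, eligible=eligible,
                            mrci=mrci, dbi=dbi, trigger_hits=hits,
                            alerts=alerts, suppressed=suppressed, trace=list(trace))


def summarize(results: list[EvaluationResult],
              registry: SuppressionRegistry | None = None) -> pd.DataFrame:
    """Per-use-case alert counts over a batch of evaluations.

    Columns: emitted, suppressed, share_pct (of all emitted alerts), and
    — when a registry with recorded responses is given — accepted and
    ignored counts. Mirrors the shape of a deployment activity report.
    """
    use_cases = ["mrci", "dbi", "trigger"]
    emitted = {u: 0 for u in use_cases}
    suppressed = {u: 0 for u in use_cases}
    owner: dict[str, str] = {}
    for r in results:
        for a in r.alerts:
            emitted[a.use_case] += 1
            owner[a.alert_id] = a.use_case
    for r in results:
        sup_ids = set(r.suppressed)
        for rec in r.trace:
            if rec.outcome == "suppressed" and rec.detail.get("alert_id") in sup_ids:
                use_case = rec.rule.split(".", 1)[1]
                suppressed[use_case] += 1
                owner.setdefault(rec.detail["alert_id"], use_case)

    accepted = {u: 0 for u in use_cases}
    ignored = {u: 0 for u in use_cases}
    if registry is not None:
        for resp in registry.responses:
            u = owner.get(resp["alert_id"])
            if u is None:
                continue
            (accepted if resp["action"] == "accepted" else ignored)[u] += 1

    total_emitted = sum(emitted.values())
    rows = []
    for u in use_cases:
        rows.append({
            "use_case": u,
            "emitted": emitted[u],
            "suppressed": suppressed[u],
            "accepted": accepted[u],
            "ignored": ignored[u],
            "share_pct": 100.0 * emitted[u] / total_emitted if total_emitted else 0.0,
        })
    return pd.DataFrame(rows).set_index("use_case")
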