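"""Patient-facing data model and JSON request parsing.

An evaluation request is one JSON document per patient carrying
demographics, the active medication orders, and timestamped laboratory
results::

    {"patient": {"id": "p1", "age": 83},
     "orders": [{"id": "o1", "vmp": {...}, "ingredient": {...},
                 "form_route": {...}, "dose": 0.25, "unit": "mg",
                 "frequency": {...}, "prn": false, "route": "oral"}],
     "labs":   [{"test": {...}, "value": 3.1, "unit": "mEq/L",
                 "observed_at": "2022-07-02T08:30:00+00:00"}]}

Concept-valued fields accept either a canonical reference
``{"id": ..., "label": ...}`` or a local code ``{"code": ...,
"vocabulary": ...}``; local codes are resolved through the KB's mapping
tables at parse time.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Union

import pydantic
from pydantic import BaseModel, Field

from .errors import CaseValidationError, UnmappedConceptError
from .kb import ConceptRef, KnowledgeBase, map_local
from .trace import Trace


class LocalCode(BaseModel):
    """A concept expressed in a local vocabulary, awaiting mapping."""

    model_config = pydantic.ConfigDict(frozen=True)

    code: str = Field(min_length=1)
    vocabulary: str = Field(min_length=1)


ConceptOrLocal = Union[ConceptRef, LocalCode]


class MedicationOrder(BaseModel):
    """One prescription line.

    ``dose`` is the single-administration dose exactly as prescribed;
    daily doses are derived downstream from dose, dose unit and the
    frequency concept's administrations-per-day.
    """

    order_id: str = Field(min_length=1)
    vmp: ConceptRef
    ingredient: ConceptRef
    form_route: ConceptRef
    dose: float = Field(gt=0)
    dose_unit: str = Field(min_length=1)
    frequency: ConceptRef
    prn: bool = False
    route: str = "oral"


class LabResult(BaseModel):
    """One laboratory observation. Timestamps must be timezone-aware."""

    test: ConceptRef
    value: float
    unit: str = Field(min_length=1)
    observed_at: _dt.datetime

    @pydantic.field_validator("observed_at")
    @classmethod
    def _tz_required(cls, v: _dt.datetime) -> _dt.datetime:
        if v.tzinfo is None:
            raise ValueError("observed_at must carry a timezone offset")
        return v


class PatientCase(BaseModel):
    """Demographics plus regimen plus labs: the unit of evaluation."""

    patient_id: str = Field(min_length=1)
    age_years: int = Field(ge=0)
    orders: list[MedicationOrder] = Field(default_factory=list)
    labs: list[LabResult] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# wire format
# ---------------------------------------------------------------------------

class _WirePatient(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    id: str = Field(min_length=1)
    age: int = Field(ge=0)


class _WireOrder(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    id: str = Field(min_length=1)
    vmp: ConceptOrLocal
    ingredient: ConceptOrLocal
    form_route: ConceptOrLocal
    dose: float = Field(gt=0)
    unit: str = Field(min_length=1)
    frequency: ConceptOrLocal
    prn: bool = False
    route: str = "oral"


class _WireLab(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    test: ConceptOrLocal
    value: float
    unit: str = Field(min_length=1)
    observed_at: _dt.datetime

    @pydantic.field_validator("observed_at")
    @classmethod
    def _tz_required(cls, v: _dt.datetime) -> _dt.datetime:
        if v.tzinfo is None:
            raise ValueError("observed_at must carry a timezone offset")
        return v


class _WireCase(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    patient: _WirePatient
    orders: list[_WireOrder] = Field(default_factory=list)
    labs: list[_WireLab] = Field(default_factory=list)


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc)


def _resolve(kb: KnowledgeBase, ref: ConceptOrLocal) -> ConceptRef:
    if isinstance(ref, LocalCode):
        return map_local(kb, ref.code, ref.vocabulary)
    return ref


def parse_case(document: str | bytes | dict, kb: KnowledgeBase, *,
               trace: Trace | None = None) -> PatientCase:
    """Validate and resolve a patient-case JSON document.

    Raises :class:`CaseValidationError` (with JSON-pointer locations) on
    schema violations and :class:`UnmappedConceptError` on an unmapped
    local code.  With a ``trace`` collector, unmapped concepts are
    instead recorded and the affected order or lab dropped, so one
    mapping gap never voids a whole evaluation.
    """
    if isinstance(document, (str, bytes)):
        try:
            data = json.loads(document)
        except json.JSONDecodeError as exc:
            raise CaseValidationError([{"pointer": "", "message": f"not valid JSON: {exc.msg} (line {exc.lineno})"}]) from exc
    else:
        data = document
    try:
        wire = _WireCase.model_validate(data)
    except pydantic.ValidationError as exc:
        raise CaseValidationError(
            [{"pointer": _pointer(e["loc"]), "message": e["msg"]} for e in exc.errors()]
        ) from exc

    orders: list[MedicationOrder] = []
    for w in wire.orders:
        try:
            orders.append(MedicationOrder(
                order_id=w.id,
                vmp=_resolve(kb, w.vmp),
                ingredient=_resolve(kb, w.ingredient),
                form_route=_resolve(kb, w.form_route),
                dose=w.dose,
                dose_unit=w.unit,
                frequency=_resolve(kb, w.frequency),
                prn=w.prn,
                route=w.route,
            ))
        except UnmappedConceptError as exc:
            if trace is None:
                raise
            trace.add("map_local", "unmapped_concept",
                      order_id=w.id, code=exc.local_code, vocabulary=exc.vocabulary)

    labs: list[LabResult] = []
    for i, w in enumerate(wire.labs):
        try:
            labs.append(LabResult(test=_resolve(kb, w.test), value=w.value,
                                  unit=w.unit, observed_at=w.observed_at))
        except UnmappedConceptError as exc:
            if trace is None:
                raise
            trace.add("map_local", "unmapped_concept",
                      lab_index=i, code=exc.local_code, vocabulary=exc.vocabulary)

    return PatientCase(patient_id=wire.patient.id, age_years=wire.patient.age,
                       orders=orders, labs=labs)


def serialize_case(case: PatientCase) -> dict:
    """Render a case back into the wire document (canonical concepts only).

    ``parse_case(serialize_case(c), kb)`` reproduces ``c`` exactly.
    """
    ref = lambda c: {"id": c.id, "label": c.label}
    return {
        "patient": {"id": case.patient_id, "age": case.age_years},
        "orders": [
            {"id": o.order_id, "vmp": ref(o.vmp), "ingredient": ref(o.ingredient),
             "form_route": ref(o.form_route), "dose": o.dose, "unit": o.dose_unit,
             "frequency": ref(o.frequency), "prn": o.prn, "route": o.route}
            for o in case.orders
        ],
        "labs": [
            {"test": ref(l.test), "value": l.value, "unit": l.unit,
             "observed_at": l.observed_at.isoformat()}
            for l in case.labs
        ],
    }
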