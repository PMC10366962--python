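"""Knowledge base of drug-appropriateness facts.

The engine's knowledge lives in three interconnected layers, mirroring how
hospital pharmacy ontologies are usually organised: drug products and their
technical data, decision-support facts (complexity weights, minimum
effective daily doses, laboratory trigger ranges, alert templates), and a
local-vocabulary layer that maps the codes an electronic prescribing system
emits onto canonical concepts.

The in-memory model is a plain typed container (:class:`KnowledgeBase`)
with three interchangeable serialisations:

``turtle``
    one RDF/Turtle graph (the ontology-style representation; also what
    :func:`query_kb` exposes to SPARQL),
``json``
    a single JSON document,
``csv-dir``
    a directory of UTF-8 CSV tables, one per entry type, header row,
    dot decimal separator.

``save_kb`` followed by ``load_kb`` is the identity on structural content
for every dialect.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import urllib.parse
from pathlib import Path
from typing import Iterable, Literal

import pydantic
from pydantic import BaseModel, Field
from rdflib import Graph, Literal as RDFLiteral, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .errors import (
    KBFormatError,
    KBIntegrityError,
    QuerySyntaxError,
    UnmappedConceptError,
)

Dialect = Literal["turtle", "json", "csv-dir"]

#: Namespace of the KB graph in the turtle dialect.
MS = Namespace("https://medscreen.example/kb#")

#: Mass units accepted for a minimum effective daily dose, after
#: :func:`normalize_unit`.
MASS_UNITS = frozenset({"ng", "mcg", "mg", "g"})

#: Route value on a trigger entry that matches any administration route.
WILDCARD_ROUTE = "*"


def normalize_unit(unit: str) -> str:
    """Canonical spelling of a dose/lab unit: trimmed, lower-case, µ→mc."""
    return unit.strip().lower().replace("µ", "mc").replace("μ", "mc")


class ConceptRef(BaseModel):
    """Reference to a canonical concept (IRI-style id plus display label)."""

    model_config = pydantic.ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    label: str = Field(min_length=1)


class FormRouteWeight(BaseModel):
    """Complexity weight of one dosage-form + administration-route combination.

    The weight is the regimen-complexity section A contribution; an oral
    tablet carries the reference weight 1 and more demanding combinations
    (solutions, inhalers, injections) carry higher weights.
    """

    concept: ConceptRef
    weight_a: float = Field(gt=0)


class FrequencyWeight(BaseModel):
    """Complexity weights of one dosing-frequency term.

    ``weight_b_scheduled`` applies to scheduled orders and
    ``weight_b_prn`` to "as needed" orders (once-daily scheduled dosing is
    the baseline, weight 1).  ``times_per_day`` is the number of
    administrations per 24 h, used to derive daily doses.
    """

    concept: ConceptRef
    weight_b_scheduled: float = Field(ge=0)
    weight_b_prn: float = Field(ge=0)
    times_per_day: float = Field(gt=0)


class ProductInstructionWeight(BaseModel):
    """Section C weight of a virtual medicinal product (extra instructions,
    e.g. relation to meals). Products without an entry contribute 0."""

    vmp: ConceptRef
    weight_c: float = Field(ge=0)


class DBIEntry(BaseModel):
    """One drug-burden list entry: an anticholinergic/sedative ingredient,
    its route, the age range it applies to, and its minimum effective daily
    dose (the δ of the burden formula D/(δ+D))."""

    ingredient: ConceptRef
    route: str = Field(min_length=1)
    age_min_years: int = 0
    age_max_years: int = 999
    min_effective_daily_dose: float = Field(gt=0)
    dose_unit: str
    base_period_hours: int = Field(default=24, gt=0)
    alert_template_id: str = Field(min_length=1)

    @pydantic.field_validator("dose_unit")
    @classmethod
    def _mass_unit(cls, v: str) -> str:
        if normalize_unit(v) not in MASS_UNITS:
            raise ValueError(f"dose_unit {v!r} is not a recognized mass unit")
        return v

    @pydantic.model_validator(mode="after")
    def _age_order(self) -> "DBIEntry":
        if self.age_min_years > self.age_max_years:
            raise ValueError("age_min_years must not exceed age_max_years")
        return self

    def matches_age(self, age_years: int) -> bool:
        # both bounds inclusive, per the conventional "65-999 years" ranges
        return self.age_min_years <= age_years <= self.age_max_years


class TriggerEntry(BaseModel):
    """One adverse-drug-event trigger: a high-alert ingredient plus the
    laboratory test and in-range interval whose violation flags a possible
    adverse event (e.g. potassium below 2.9 mEq/L under a loop diuretic)."""

    ingredient: ConceptRef
    route: str = WILDCARD_ROUTE
    age_min_years: int = 0
    age_max_years: int = 999
    lab_test: ConceptRef
    lab_unit: str = Field(min_length=1)
    low: float
    high: float
    alert_template_id: str = Field(min_length=1)

    @pydantic.model_validator(mode="after")
    def _bounds(self) -> "TriggerEntry":
        if self.low > self.high:
            raise ValueError("low must not exceed high")
        if self.age_min_years > self.age_max_years:
            raise ValueError("age_min_years must not exceed age_max_years")
        return self

    def matches_age(self, age_years: int) -> bool:
        return self.age_min_years <= age_years <= self.age_max_years

    def matches_route(self, route: str) -> bool:
        return self.route in ("", WILDCARD_ROUTE) or self.route == route


AlertLevel = Literal["contraindicated", "moderate", "low", "risk_minimization"]
Intervention = Literal["global_drug", "specific_drug"]


class AlertTemplate(BaseModel):
    """Static content of a decision-support alert: description,
    recommendation, source and date, clinical-relevance level and whether
    the intervention targets a specific drug or the whole regimen."""

    id: str = Field(min_length=1)
    description: str = Field(min_length=1)
    recommendation: str = ""
    source: str = ""
    updated_date: _dt.date = _dt.date(2022, 7, 1)
    link: str = ""
    level: AlertLevel
    intervention: Intervention


class LocalConceptMap(BaseModel):
    """Mapping of one local (code, vocabulary) pair to a canonical concept."""

    local_code: str = Field(min_length=1)
    local_vocabulary: str = Field(min_length=1)
    canonical: ConceptRef


class UnitConversion(BaseModel):
    """Multiplicative factor converting ``from_unit`` to ``to_unit``."""

    from_unit: str
    to_unit: str
    factor: float = Field(gt=0)


class Thresholds(BaseModel):
    """Alerting cut-offs: regimen-complexity total, drug-burden total, and
    the minimum patient age for any screening to apply."""

    mrci_alert: float = Field(default=40.0, gt=0)
    dbi_alert: float = Field(default=1.0, gt=0)
    min_age_years: int = Field(default=65, gt=0)


class KnowledgeBase(BaseModel):
    """Typed container of every appropriateness fact the engine consumes."""

    version: str = "0"
    form_route_weights: list[FormRouteWeight] = Field(default_factory=list)
    frequency_weights: list[FrequencyWeight] = Field(default_factory=list)
    product_instruction_weights: list[ProductInstructionWeight] = Field(default_factory=list)
    dbi_entries: list[DBIEntry] = Field(default_factory=list)
    trigger_entries: list[TriggerEntry] = Field(default_factory=list)
    alert_templates: list[AlertTemplate] = Field(default_factory=list)
    concept_maps: list[LocalConceptMap] = Field(default_factory=list)
    unit_conversions: list[UnitConversion] = Field(default_factory=list)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    #: templates used for the regimen-level complexity and burden alerts
    mrci_template_id: str = ""
    dbi_template_id: str = ""

    # -- lookups ---------------------------------------------------------

    def template(self, template_id: str) -> AlertTemplate | None:
        for t in self.alert_templates:
            if t.id == template_id:
                return t
        return None

    def form_route_weight(self, concept_id: str) -> FormRouteWeight | None:
        for w in self.form_route_weights:
            if w.concept.id == concept_id:
                return w
        return None

    def frequency_weight(self, concept_id: str) -> FrequencyWeight | None:
        for w in self.frequency_weights:
            if w.concept.id == concept_id:
                return w
        return None

    def instruction_weight(self, vmp_id: str) -> ProductInstructionWeight | None:
        for w in self.product_instruction_weights:
            if w.vmp.id == vmp_id:
                return w
        return None

    def conversion_factor(self, from_unit: str, to_unit: str) -> float | None:
        """Factor converting ``from_unit`` to ``to_unit``; identity pairs
        always convert with factor 1. ``None`` when no path exists."""
        a, b = normalize_unit(from_unit), normalize_unit(to_unit)
        if a == b:
            return 1.0
        for c in self.unit_conversions:
            if normalize_unit(c.from_unit) == a and normalize_unit(c.to_unit) == b:
                return c.factor
        return None

    def concepts(self) -> dict[str, ConceptRef]:
        """All canonical concepts referenced anywhere in the KB, by id."""
        out: dict[str, ConceptRef] = {}
        for w in self.form_route_weights:
            out[w.concept.id] = w.concept
        for w in self.frequency_weights:
            out[w.concept.id] = w.concept
        for w in self.product_instruction_weights:
            out[w.vmp.id] = w.vmp
        for e in self.dbi_entries:
            out[e.ingredient.id] = e.ingredient
        for e in self.trigger_entries:
            out[e.ingredient.id] = e.ingredient
            out[e.lab_test.id] = e.lab_test
        return out

    # -- integrity -------------------------------------------------------

    def validate_integrity(self) -> None:
        """Check cross-reference invariants; raise :class:`KBIntegrityError`
        listing every offender if any fail.

        Checked: alert-template references resolve (including the
        regimen-level template ids when set); at most one section-A weight
        per form/route concept and one frequency/instruction weight per
        concept; a concept id never maps to two different labels; local
        (code, vocabulary) pairs are unique and map to concepts known to
        the KB.
        """
        offenders: list[str] = []
        template_ids = {t.id for t in self.alert_templates}
        dup_t = {t for t in template_ids if sum(x.id == t for x in self.alert_templates) > 1}
        offenders += [f"duplicate alert template id {t!r}" for t in sorted(dup_t)]

        for i, e in enumerate(self.dbi_entries):
            if e.alert_template_id not in template_ids:
                offenders.append(f"dbi_entries[{i}] references missing template {e.alert_template_id!r}")
        for i, e in enumerate(self.trigger_entries):
            if e.alert_template_id not in template_ids:
                offenders.append(f"trigger_entries[{i}] references missing template {e.alert_template_id!r}")
        for name, tid in (("mrci_template_id", self.mrci_template_id), ("dbi_template_id", self.dbi_template_id)):
            if tid and tid not in template_ids:
                offenders.append(f"{name} references missing template {tid!r}")

        for name, entries in (
            ("form_route_weights", [w.concept.id for w in self.form_route_weights]),
            ("frequency_weights", [w.concept.id for w in self.frequency_weights]),
            ("product_instruction_weights", [w.vmp.id for w in self.product_instruction_weights]),
        ):
            seen: set[str] = set()
            for cid in entries:
                if cid in seen:
                    offenders.append(f"{name} has more than one entry for concept {cid!r}")
                seen.add(cid)

        labels: dict[str, str] = {}
        for ref in self._all_concept_refs():
            if ref.id in labels and labels[ref.id] != ref.label:
                offenders.append(f"concept {ref.id!r} carries conflicting labels {labels[ref.id]!r} / {ref.label!r}")
            labels.setdefault(ref.id, ref.label)

        known = set(self.concepts())
        seen_local: set[tuple[str, str]] = set()
        for m in self.concept_maps:
            key = (m.local_code, m.local_vocabulary)
            if key in seen_local:
                offenders.append(f"duplicate local mapping for {key!r}")
            seen_local.add(key)
            if m.canonical.id not in known:
                offenders.append(
                    f"local mapping {key!r} targets concept {m.canonical.id!r} absent from the KB"
                )

        if offenders:
            raise KBIntegrityError(offenders)

    def _all_concept_refs(self) -> Iterable[ConceptRef]:
        for w in self.form_route_weights:
            yield w.concept
        for w in self.frequency_weights:
            yield w.concept
        for w in self.product_instruction_weights:
            yield w.vmp
        for e in self.dbi_entries:
            yield e.ingredient
        for e in self.trigger_entries:
            yield e.ingredient
            yield e.lab_test

    def canonical(self) -> "KnowledgeBase":
        """Copy with every collection in a deterministic sort order, for
        structural-equality comparisons across serialisation dialects."""
        kb = self.model_copy(deep=True)
        kb.form_route_weights.sort(key=lambda w: w.concept.id)
        kb.frequency_weights.sort(key=lambda w: w.concept.id)
        kb.product_instruction_weights.sort(key=lambda w: w.vmp.id)
        kb.dbi_entries.sort(key=lambda e: (e.ingredient.id, e.route, e.age_min_years, e.min_effective_daily_dose))
        kb.trigger_entries.sort(key=lambda e: (e.ingredient.id, e.route, e.lab_test.id, e.low, e.high))
        kb.alert_templates.sort(key=lambda t: t.id)
        kb.concept_maps.sort(key=lambda m: (m.local_vocabulary, m.local_code))
        kb.unit_conversions.sort(key=lambda c: (c.from_unit, c.to_unit))
        return kb


def map_local(kb: KnowledgeBase, local_code: str, vocabulary: str) -> ConceptRef:
    """Resolve a local concept code to its canonical concept.

    The key is the (code, vocabulary) pair: the same code may map
    differently in different source vocabularies.  Raises
    :class:`UnmappedConceptError` when no mapping exists — silent loss
    would hide gaps in the mapping tables.
    """
    for m in kb.concept_maps:
        if m.local_code == local_code and m.local_vocabulary == vocabulary:
            return m.canonical
    raise UnmappedConceptError(local_code, vocabulary)


# ---------------------------------------------------------------------------
# RDF graph materialisation
# ---------------------------------------------------------------------------

def _concept_uri(concept_id: str) -> URIRef:
    if "://" in concept_id:
        return URIRef(concept_id)
    return URIRef(str(MS) + "concept/" + urllib.parse.quote(concept_id, safe=""))


def _num(value: float) -> RDFLiteral:
    # xsd:double literals built from the float itself round-trip exactly
    return RDFLiteral(value, datatype=XSD.double)


def _add_concept(g: Graph, ref: ConceptRef) -> URIRef:
    node = _concept_uri(ref.id)
    g.add((node, RDF.type, MS.Concept))
    g.add((node, MS.conceptId, RDFLiteral(ref.id)))
    g.add((node, RDFS.label, RDFLiteral(ref.label)))
    return node


def to_graph(kb: KnowledgeBase) -> Graph:
    """Materialise the KB as an RDF graph in the ``ms:`` vocabulary."""
    g = Graph()
    g.bind("ms", MS)

    root = MS["kb"]
    g.add((root, RDF.type, MS.KnowledgeBase))
    g.add((root, MS.version, RDFLiteral(kb.version)))
    g.add((root, MS.mrciAlertThreshold, _num(kb.thresholds.mrci_alert)))
    g.add((root, MS.dbiAlertThreshold, _num(kb.thresholds.dbi_alert)))
    g.add((root, MS.minAgeYears, RDFLiteral(kb.thresholds.min_age_years)))
    if kb.mrci_template_id:
        g.add((root, MS.mrciTemplate, RDFLiteral(kb.mrci_template_id)))
    if kb.dbi_template_id:
        g.add((root, MS.dbiTemplate, RDFLiteral(kb.dbi_template_id)))

    for w in kb.form_route_weights:
        node = MS["formRouteWeight/" + urllib.parse.quote(w.concept.id, safe="")]
        g.add((node, RDF.type, MS.FormRouteWeight))
        g.add((node, MS.concept, _add_concept(g, w.concept)))
        g.add((node, MS.mrciAWeight, _num(w.weight_a)))

    for w in kb.frequency_weights:
        node = MS["frequencyWeight/" + urllib.parse.quote(w.concept.id, safe="")]
        g.add((node, RDF.type, MS.FrequencyWeight))
        g.add((node, MS.concept, _add_concept(g, w.concept)))
        g.add((node, MS.mrciB, _num(w.weight_b_scheduled)))
        g.add((node, MS.mrciBPrn, _num(w.weight_b_prn)))
        g.add((node, MS.timesPerDay, _num(w.times_per_day)))

    for w in kb.product_instruction_weights:
        node = MS["instructionWeight/" + urllib.parse.quote(w.vmp.id, safe="")]
        g.add((node, RDF.type, MS.ProductInstructionWeight))
        g.add((node, MS.vmp, _add_concept(g, w.vmp)))
        g.add((node, MS.mrciC, _num(w.weight_c)))

    for i, e in enumerate(kb.dbi_entries):
        node = MS[f"dbiEntry/{i}"]
        g.add((node, RDF.type, MS.DBIEntry))
        g.add((node, MS.ingredient, _add_concept(g, e.ingredient)))
        g.add((node, MS.route, RDFLiteral(e.route)))
        g.add((node, MS.ageMinYears, RDFLiteral(e.age_min_years)))
        g.add((node, MS.ageMaxYears, RDFLiteral(e.age_max_years)))
        g.add((node, MS.minEffectiveDailyDose, _num(e.min_effective_daily_dose)))
        g.add((node, MS.doseUnit, RDFLiteral(e.dose_unit)))
        g.add((node, MS.basePeriodHours, RDFLiteral(e.base_period_hours)))
        g.add((node, MS.alertTemplate, RDFLiteral(e.alert_template_id)))

    for i, e in enumerate(kb.trigger_entries):
        node = MS[f"triggerEntry/{i}"]
        g.add((node, RDF.type, MS.TriggerEntry))
        g.add((node, MS.ingredient, _add_concept(g, e.ingredient)))
        g.add((node, MS.route, RDFLiteral(e.route)))
        g.add((node, MS.ageMinYears, RDFLiteral(e.age_min_years)))
        g.add((node, MS.ageMaxYears, RDFLiteral(e.age_max_years)))
        g.add((node, MS.labTest, _add_concept(g, e.lab_test)))
        g.add((node, MS.labUnit, RDFLiteral(e.lab_unit)))
        g.add((node, MS.lowValue, _num(e.low)))
        g.add((node, MS.highValue, _num(e.high)))
        g.add((node, MS.alertTemplate, RDFLiteral(e.alert_template_id)))

    for t in kb.alert_templates:
        node = MS["alertTemplate/" + urllib.parse.quote(t.id, safe="")]
        g.add((node, RDF.type, MS.AlertTemplate))
        g.add((node, MS.templateId, RDFLiteral(t.id)))
        g.add((node, MS.description, RDFLiteral(t.description)))
        g.add((node, MS.recommendation, RDFLiteral(t.recommendation)))
        g.add((node, MS.source, RDFLiteral(t.source)))
        g.add((node, MS.updatedDate, RDFLiteral(t.updated_date, datatype=XSD.date)))
        g.add((node, MS.link, RDFLiteral(t.link)))
        g.add((node, MS.level, RDFLiteral(t.level)))
        g.add((node, MS.intervention, RDFLiteral(t.intervention)))

    for i, m in enumerate(kb.concept_maps):
        node = MS[f"localMap/{i}"]
        g.add((node, RDF.type, MS.LocalConceptMap))
        g.add((node, MS.localCode, RDFLiteral(m.local_code)))
        g.add((node, MS.localVocabulary, RDFLiteral(m.local_vocabulary)))
        g.add((node, MS.canonical, _add_concept(g, m.canonical)))

    for i, c in enumerate(kb.unit_conversions):
        node = MS[f"unitConversion/{i}"]
        g.add((node, RDF.type, MS.UnitConversion))
        g.add((node, MS.fromUnit, RDFLiteral(c.from_unit)))
        g.add((node, MS.toUnit, RDFLiteral(c.to_unit)))
        g.add((node, MS.conversionFactor, _num(c.factor)))

    return g


def _read_concept(g: Graph, node) -> ConceptRef:
    cid = g.value(node, MS.conceptId)
    label = g.value(node, RDFS.label)
    return ConceptRef(id=str(cid), label=str(label))


def from_graph(g: Graph) -> KnowledgeBase:
    """Rebuild the typed KB from an RDF graph produced by :func:`to_graph`."""

    def val(node, prop, default=None):
        v = g.value(node, prop)
        return default if v is None else v.toPython()

    kb = KnowledgeBase()
    root = next(g.subjects(RDF.type, MS.KnowledgeBase), None)
    if root is not None:
        kb.version = str(val(root, MS.version, "0"))
        kb.thresholds = Thresholds(
            mrci_alert=float(val(root, MS.mrciAlertThreshold, 40.0)),
            dbi_alert=float(val(root, MS.dbiAlertThreshold, 1.0)),
            min_age_years=int(val(root, MS.minAgeYears, 65)),
        )
        kb.mrci_template_id = str(val(root, MS.mrciTemplate, ""))
        kb.dbi_template_id = str(val(root, MS.dbiTemplate, ""))

    for node in g.subjects(RDF.type, MS.FormRouteWeight):
        kb.form_route_weights.append(FormRouteWeight(
            concept=_read_concept(g, g.value(node, MS.concept)),
            weight_a=float(val(node, MS.mrciAWeight)),
        ))
    for node in g.subjects(RDF.type, MS.FrequencyWeight):
        kb.frequency_weights.append(FrequencyWeight(
            concept=_read_concept(g, g.value(node, MS.concept)),
            weight_b_scheduled=float(val(node, MS.mrciB)),
            weight_b_prn=float(val(node, MS.mrciBPrn)),
            times_per_day=float(val(node, MS.timesPerDay)),
        ))
    for node in g.subjects(RDF.type, MS.ProductInstructionWeight):
        kb.product_instruction_weights.append(ProductInstructionWeight(
            vmp=_read_concept(g, g.value(node, MS.vmp)),
            weight_c=float(val(node, MS.mrciC)),
        ))
    for node in g.subjects(RDF.type, MS.DBIEntry):
        kb.dbi_entries.append(DBIEntry(
            ingredient=_read_concept(g, g.value(node, MS.ingredient)),
            route=str(val(node, MS.route)),
            age_min_years=int(val(node, MS.ageMinYears)),
            age_max_years=int(val(node, MS.ageMaxYears)),
            min_effective_daily_dose=float(val(node, MS.minEffectiveDailyDose)),
            dose_unit=str(val(node, MS.doseUnit)),
            base_period_hours=int(val(node, MS.basePeriodHours)),
            alert_template_id=str(val(node, MS.alertTemplate)),
        ))
    for node in g.subjects(RDF.type, MS.TriggerEntry):
        kb.trigger_entries.append(TriggerEntry(
            ingredient=_read_concept(g, g.value(node, MS.ingredient)),
            route=str(val(node, MS.route)),
            age_min_years=int(val(node, MS.ageMinYears)),
            age_max_years=int(val(node, MS.ageMaxYears)),
            lab_test=_read_concept(g, g.value(node, MS.labTest)),
            lab_unit=str(val(node, MS.labUnit)),
            low=float(val(node, MS.lowValue)),
            high=float(val(node, MS.highValue)),
            alert_template_id=str(val(node, MS.alertTemplate)),
        ))
    for node in g.subjects(RDF.type, MS.AlertTemplate):
        kb.alert_templates.append(AlertTemplate(
            id=str(val(node, MS.templateId)),
            description=str(val(node, MS.description)),
            recommendation=str(val(node, MS.recommendation, "")),
            source=str(val(node, MS.source, "")),
            updated_date=val(node, MS.updatedDate),
            link=str(val(node, MS.link, "")),
            level=str(val(node, MS.level)),
            intervention=str(val(node, MS.intervention)),
        ))
    for node in g.subjects(RDF.type, MS.LocalConceptMap):
        kb.concept_maps.append(LocalConceptMap(
            local_code=str(val(node, MS.localCode)),
            local_vocabulary=str(val(node, MS.localVocabulary)),
            canonical=_read_concept(g, g.value(node, MS.canonical)),
        ))
    for node in g.subjects(RDF.type, MS.UnitConversion):
        kb.unit_conversions.append(UnitConversion(
            from_unit=str(val(node, MS.fromUnit)),
            to_unit=str(val(node, MS.toUnit)),
            factor=float(val(node, MS.conversionFactor)),
        ))
    return kb.canonical()


def query_kb(kb: KnowledgeBase, query: str) -> list[dict]:
    """Run a SPARQL query against the KB's RDF materialisation.

    Returns one dict per result row, keyed by variable name, with RDF
    terms converted to Python values.
    """
    g = to_graph(kb)
    try:
        result = g.query(query)
    except Exception as exc:  # rdflib raises assorted parse exception types
        raise QuerySyntaxError(f"malformed SPARQL query: {exc}") from exc
    rows = []
    for binding in result:
        row = {}
        for var, term in zip(result.vars, binding):
            row[str(var)] = term.toPython() if term is not None else None
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

_CSV_FILES = {
    "meta": ["key", "value"],
    "form_route_weights": ["concept_id", "concept_label", "weight_a"],
    "frequency_weights": ["concept_id", "concept_label", "weight_b_scheduled", "weight_b_prn", "times_per_day"],
    "product_instruction_weights": ["vmp_id", "vmp_label", "weight_c"],
    "dbi_entries": ["ingredient_id", "ingredient_label", "route", "age_min_years", "age_max_years",
                    "min_effective_daily_dose", "dose_unit", "base_period_hours", "alert_template_id"],
    "trigger_entries": ["ingredient_id", "ingredient_label", "route", "age_min_years", "age_max_years",
                        "lab_test_id", "lab_test_label", "lab_unit", "low", "high", "alert_template_id"],
    "alert_templates": ["id", "description", "recommendation", "source", "updated_date", "link",
                        "level", "intervention"],
    "concept_maps": ["local_code", "local_vocabulary", "canonical_id", "canonical_label"],
    "unit_conversions": ["from_unit", "to_unit", "factor"],
}


def _save_csv_dir(kb: KnowledgeBase, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)

    def write(name: str, rows: list[list]) -> None:
        with open(path / f"{name}.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_FILES[name])
            w.writerows(rows)

    write("meta", [
        ["version", kb.version],
        ["mrci_alert", kb.thresholds.mrci_alert],
        ["dbi_alert", kb.thresholds.dbi_alert],
        ["min_age_years", kb.thresholds.min_age_years],
        ["mrci_template_id", kb.mrci_template_id],
        ["dbi_template_id", kb.dbi_template_id],
    ])
    write("form_route_weights",
          [[w.concept.id, w.concept.label, w.weight_a] for w in kb.form_route_weights])
    write("frequency_weights",
          [[w.concept.id, w.concept.label, w.weight_b_scheduled, w.weight_b_prn, w.times_per_day]
           for w in kb.frequency_weights])
    write("product_instruction_weights",
          [[w.vmp.id, w.vmp.label, w.weight_c] for w in kb.product_instruction_weights])
    write("dbi_entries",
          [[e.ingredient.id, e.ingredient.label, e.route, e.age_min_years, e.age_max_years,
            e.min_effective_daily_dose, e.dose_unit, e.base_period_hours, e.alert_template_id]
           for e in kb.dbi_entries])
    write("trigger_entries",
          [[e.ingredient.id, e.ingredient.label, e.route, e.age_min_years, e.age_max_years,
            e.lab_test.id, e.lab_test.label, e.lab_unit, e.low, e.high, e.alert_template_id]
           for e in kb.trigger_entries])
    write("alert_templates",
          [[t.id, t.description, t.recommendation, t.source, t.updated_date.isoformat(), t.link,
            t.level, t.intervention] for t in kb.alert_templates])
    write("concept_maps",
          [[m.local_code, m.local_vocabulary, m.canonical.id, m.canonical.label]
           for m in kb.concept_maps])
    write("unit_conversions",
          [[c.from_unit, c.to_unit, c.factor] for c in kb.unit_conversions])


def _load_csv_dir(path: Path) -> KnowledgeBase:
    def read(name: str) -> list[dict]:
        fpath = path / f"{name}.csv"
        if not fpath.exists():
            raise KBFormatError(f"missing table {name}.csv", path=str(fpath))
        with open(fpath, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = set(_CSV_FILES[name]) - set(reader.fieldnames or [])
            if missing:
                raise KBFormatError(
                    f"table {name}.csv lacks column(s) {sorted(missing)}", path=str(fpath), line=1)
            try:
                return list(reader)
            except csv.Error as exc:
                raise KBFormatError(str(exc), path=str(fpath), line=reader.line_num) from exc

    def build(name: str, factory):
        out = []
        fpath = str(path / f"{name}.csv")
        for i, row in enumerate(read(name)):
            try:
                out.append(factory(row))
            except (pydantic.ValidationError, ValueError) as exc:
                raise KBFormatError(f"bad row: {exc}", path=fpath, line=i + 2) from exc
        return out

    kb = KnowledgeBase()
    meta = {r["key"]: r["value"] for r in read("meta")}
    kb.version = meta.get("version", "0")
    kb.mrci_template_id = meta.get("mrci_template_id", "")
    kb.dbi_template_id = meta.get("dbi_template_id", "")
    kb.thresholds = Thresholds(
        mrci_alert=float(meta.get("mrci_alert", 40)),
        dbi_alert=float(meta.get("dbi_alert", 1)),
        min_age_years=int(meta.get("min_age_years", 65)),
    )
    kb.form_route_weights = build("form_route_weights", lambda r: FormRouteWeight(
        concept=ConceptRef(id=r["concept_id"], label=r["concept_label"]),
        weight_a=float(r["weight_a"])))
    kb.frequency_weights = build("frequency_weights", lambda r: FrequencyWeight(
        concept=ConceptRef(id=r["concept_id"], label=r["concept_label"]),
        weight_b_scheduled=float(r["weight_b_scheduled"]),
        weight_b_prn=float(r["weight_b_prn"]),
        times_per_day=float(r["times_per_day"])))
    kb.product_instruction_weights = build("product_instruction_weights", lambda r: ProductInstructionWeight(
        vmp=ConceptRef(id=r["vmp_id"], label=r["vmp_label"]),
        weight_c=float(r["weight_c"])))
    kb.dbi_entries = build("dbi_entries", lambda r: DBIEntry(
        ingredient=ConceptRef(id=r["ingredient_id"], label=r["ingredient_label"]),
        route=r["route"],
        age_min_years=int(r["age_min_years"]),
        age_max_years=int(r["age_max_years"]),
        min_effective_daily_dose=float(r["min_effective_daily_dose"]),
        dose_unit=r["dose_unit"],
        base_period_hours=int(r["base_period_hours"]),
        alert_template_id=r["alert_template_id"]))
    kb.trigger_entries = build("trigger_entries", lambda r: TriggerEntry(
        ingredient=ConceptRef(id=r["ingredient_id"], label=r["ingredient_label"]),
        route=r["route"],
        age_min_years=int(r["age_min_years"]),
        age_max_years=int(r["age_max_years"]),
        lab_test=ConceptRef(id=r["lab_test_id"], label=r["lab_test_label"]),
        lab_unit=r["lab_unit"],
        low=float(r["low"]),
        high=float(r["high"]),
        alert_template_id=r["alert_template_id"]))
    kb.alert_templates = build("alert_templates", lambda r: AlertTemplate(
        id=r["id"], description=r["description"], recommendation=r["recommendation"],
        source=r["source"], updated_date=_dt.date.fromisoformat(r["updated_date"]),
        link=r["link"], level=r["level"], intervention=r["intervention"]))
    kb.concept_maps = build("concept_maps", lambda r: LocalConceptMap(
        local_code=r["local_code"], local_vocabulary=r["local_vocabulary"],
        canonical=ConceptRef(id=r["canonical_id"], label=r["canonical_label"])))
    kb.unit_conversions = build("unit_conversions", lambda r: UnitConversion(
        from_unit=r["from_unit"], to_unit=r["to_unit"], factor=float(r["factor"])))
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path, dialect: Dialect = "json") -> None:
    """Serialise the KB to ``path`` in the given dialect.

    The file(s) written satisfy the round-trip contract: ``load_kb`` on
    the same path and dialect returns a structurally equal KB.
    """
    path = Path(path)
    if dialect == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(kb.model_dump(mode="json"), indent=1), encoding="utf-8")
    elif dialect == "turtle":
        path.parent.mkdir(parents=True, exist_ok=True)
        to_graph(kb).serialize(destination=str(path), format="turtle")
    elif dialect == "csv-dir":
        _save_csv_dir(kb, path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def load_kb(path: str | Path, dialect: Dialect = "json") -> KnowledgeBase:
    """Load a KB from ``path``; validates referential integrity.

    Raises :class:`KBFormatError` on parse failure (naming file and line
    when available) and :class:`KBIntegrityError` on dangling references.
    """
    path = Path(path)
    if not path.exists():
        raise KBFormatError("path does not exist", path=str(path))
    if dialect == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise KBFormatError(exc.msg, path=str(path), line=exc.lineno) from exc
        try:
            kb = KnowledgeBase.model_validate(data)
        except pydantic.ValidationError as exc:
            raise KBFormatError(f"invalid KB document: {exc}", path=str(path)) from exc
    elif dialect == "turtle":
        g = Graph()
        try:
            g.parse(str(path), format="turtle")
        except Exception as exc:
            line = getattr(exc, "lines", None)
            raise KBFormatError(f"turtle parse failure: {exc}", path=str(path),
                                line=line if isinstance(line, int) else None) from exc
        try:
            kb = from_graph(g)
        except (pydantic.ValidationError, TypeError, ValueError) as exc:
            raise KBFormatError(f"graph does not describe a valid KB: {exc}", path=str(path)) from exc
    elif dialect == "csv-dir":
        if not path.is_dir():
            raise KBFormatError("csv-dir dialect requires a directory", path=str(path))
        kb = _load_csv_dir(path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")
    kb.validate_integrity()
    return kb
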