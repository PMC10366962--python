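"""Demo knowledge base and synthetic patient generator.

The packaged demo KB carries the handful of published exemplar facts the
engine's decision rules are documented with — the oral tablet as the
section-A reference weight 1, once-daily dosing as the section-B
baseline 1, alprazolam (oral, age 65-999) with a minimum effective daily
dose of 0.5 mg, and the furosemide triggers on serum glucose
(0–110 mg/dL) and potassium (low bound 2.9 mEq/L) — plus clearly marked
synthetic entries whose concept ids carry a ``demo:`` prefix. Synthetic
entries use invented drug names so no invented weight can be mistaken
for a clinically validated one.

:func:`generate_cases` produces seeded, reproducible patient cases
shaped like a polypharmacy internal-medicine ward population (old
patients on many concurrent medications), with controllable fractions of
burden-listed drugs, trigger drugs and abnormal laboratory values.
"""

from __future__ import annotations

import datetime as _dt
import random

from pydantic import BaseModel, Field, model_validator

from .kb import (
    AlertTemplate,
    ConceptRef,
    DBIEntry,
    FormRouteWeight,
    FrequencyWeight,
    KnowledgeBase,
    LocalConceptMap,
    ProductInstructionWeight,
    TriggerEntry,
    UnitConversion,
)
from .patient import LabResult, MedicationOrder, PatientCase

# exemplar concepts (published reference values attach to these)
ORAL_TABLET = ConceptRef(id="form:oral-tablet", label="Oral tablet")
ONCE_DAILY = ConceptRef(id="freq:once-daily", label="Once daily")
ALPRAZOLAM = ConceptRef(id="ing:alprazolam", label="Alprazolam")
FUROSEMIDE = ConceptRef(id="ing:furosemide", label="Furosemide")
OMEPRAZOLE_20 = ConceptRef(id="vmp:omeprazole-20mg-capsule", label="Omeprazole 20mg capsule")
SERUM_GLUCOSE = ConceptRef(id="lab:serum-glucose", label="Serum glucose")
POTASSIUM = ConceptRef(id="lab:potassium", label="Potassium")

# synthetic concepts (invented names, demo: prefix)
DEMO_ORAL_SOLUTION = ConceptRef(id="demo:form/oral-solution", label="Oral solution (demo)")
DEMO_INHALER = ConceptRef(id="demo:form/dry-powder-inhaler", label="Dry powder inhaler (demo)")
DEMO_INJECTION = ConceptRef(id="demo:form/subcutaneous-injection", label="Subcutaneous injection (demo)")
DEMO_TWICE_DAILY = ConceptRef(id="demo:freq/twice-daily", label="Twice daily (demo)")
DEMO_THREE_TIMES_DAILY = ConceptRef(id="demo:freq/three-times-daily", label="Three times daily (demo)")
DEMO_EVERY_12H = ConceptRef(id="demo:freq/every-12h-with-meals", label="Every 12 h with meals (demo)")
DEMO_SEDANOL = ConceptRef(id="demo:ing/sedanol", label="Sedanol (demo sedative)")
DEMO_CHOLINEX = ConceptRef(id="demo:ing/cholinex", label="Cholinex (demo anticholinergic)")
DEMO_PLAINOL = ConceptRef(id="demo:ing/plainol", label="Plainol (demo, burden-free)")
DEMO_SODIUM = ConceptRef(id="demo:lab/sodium", label="Sodium (demo)")
DEMO_VMP_SEDANOL = ConceptRef(id="demo:vmp/sedanol-5mg-tablet", label="Sedanol 5mg tablet (demo)")
DEMO_VMP_PLAINOL = ConceptRef(id="demo:vmp/plainol-10mg-tablet", label="Plainol 10mg tablet (demo)")


def build_demo_kb() -> KnowledgeBase:
    """Deterministic demo KB: the published exemplars plus ``demo:``
    synthetic entries, enough to exercise every decision rule offline."""
    kb = KnowledgeBase(
        version="demo-1.0",
        mrci_template_id="tpl-mrci-high",
        dbi_template_id="tpl-dbi-high",
        form_route_weights=[
            FormRouteWeight(concept=ORAL_TABLET, weight_a=1.0),
            FormRouteWeight(concept=DEMO_ORAL_SOLUTION, weight_a=2.0),
            FormRouteWeight(concept=DEMO_INHALER, weight_a=3.0),
            FormRouteWeight(concept=DEMO_INJECTION, weight_a=4.0),
        ],
        frequency_weights=[
            FrequencyWeight(concept=ONCE_DAILY, weight_b_scheduled=1.0,
                            weight_b_prn=0.5, times_per_day=1.0),
            FrequencyWeight(concept=DEMO_TWICE_DAILY, weight_b_scheduled=2.0,
                            weight_b_prn=1.0, times_per_day=2.0),
            FrequencyWeight(concept=DEMO_THREE_TIMES_DAILY, weight_b_scheduled=3.0,
                            weight_b_prn=1.5, times_per_day=3.0),
            # meal-related qualifier folded into the B weight
            FrequencyWeight(concept=DEMO_EVERY_12H, weight_b_scheduled=3.0,
                            weight_b_prn=1.5, times_per_day=2.0),
        ],
        product_instruction_weights=[
            ProductInstructionWeight(vmp=OMEPRAZOLE_20, weight_c=1.0),
            ProductInstructionWeight(vmp=DEMO_VMP_SEDANOL, weight_c=2.0),
        ],
        dbi_entries=[
            DBIEntry(ingredient=ALPRAZOLAM, route="oral",
                     age_min_years=65, age_max_years=999,
                     min_effective_daily_dose=0.5, dose_unit="mg",
                     base_period_hours=24, alert_template_id="tpl-dbi-high"),
            DBIEntry(ingredient=DEMO_SEDANOL, route="oral",
                     age_min_years=65, age_max_years=999,
                     min_effective_daily_dose=10.0, dose_unit="mg",
                     base_period_hours=24, alert_template_id="tpl-dbi-high"),
            DBIEntry(ingredient=DEMO_CHOLINEX, route="oral",
                     age_min_years=65, age_max_years=999,
                     min_effective_daily_dose=2.0, dose_unit="mg",
                     base_period_hours=24, alert_template_id="tpl-dbi-high"),
        ],
        trigger_entries=[
            TriggerEntry(ingredient=FUROSEMIDE, route="parenteral",
                         age_min_years=65, age_max_years=999,
                         lab_test=SERUM_GLUCOSE, lab_unit="mg/dL",
                         low=0.0, high=110.0, alert_template_id="tpl-trig-glucose"),
            TriggerEntry(ingredient=FUROSEMIDE, route="*",
                         age_min_years=65, age_max_years=999,
                         lab_test=POTASSIUM, lab_unit="mEq/L",
                         low=2.9, high=5.0, alert_template_id="tpl-trig-potassium"),
            TriggerEntry(ingredient=DEMO_CHOLINEX, route="oral",
                         age_min_years=65, age_max_years=999,
                         lab_test=DEMO_SODIUM, lab_unit="mmol/L",
                         low=135.0, high=145.0, alert_template_id="tpl-trig-sodium"),
        ],
        alert_templates=[
            AlertTemplate(id="tpl-mrci-high",
                          description="High medication regimen complexity",
                          recommendation="Review total treatment and simplify the regimen where possible.",
                          source="demo knowledge base",
                          updated_date=_dt.date(2022, 7, 1),
                          level="risk_minimization", intervention="global_drug"),
            AlertTemplate(id="tpl-dbi-high",
                          description="High anticholinergic and sedative drug burden",
                          recommendation="Consider deprescribing or dose reduction of the listed drugs.",
                          source="demo knowledge base",
                          updated_date=_dt.date(2022, 7, 1),
                          level="risk_minimization", intervention="specific_drug"),
            AlertTemplate(id="tpl-trig-glucose",
                          description="Serum glucose outside the expected range under a high-alert drug",
                          recommendation="Assess for a possible adverse drug event.",
                          source="demo knowledge base",
                          updated_date=_dt.date(2022, 7, 1),
                          level="low", intervention="specific_drug"),
            AlertTemplate(id="tpl-trig-potassium",
                          description="Potassium below the expected range under a loop diuretic",
                          recommendation="Assess for hypokalemia as a possible adverse drug event.",
                          source="demo knowledge base",
                          updated_date=_dt.date(2022, 7, 1),
                          level="low", intervention="specific_drug"),
            AlertTemplate(id="tpl-trig-sodium",
                          description="Sodium outside the expected range under a demo drug",
                          recommendation="Assess for a possible adverse drug event (synthetic demo rule).",
                          source="demo knowledge base",
                          updated_date=_dt.date(2022, 7, 1),
                          level="low", intervention="specific_drug"),
        ],
        concept_maps=[
            LocalConceptMap(local_code="LOC-TAB-ORAL", local_vocabulary="demo",
                            canonical=ORAL_TABLET),
            LocalConceptMap(local_code="LOC-FREQ-QD", local_vocabulary="demo",
                            canonical=ONCE_DAILY),
            LocalConceptMap(local_code="LOC-ALPRAZ", local_vocabulary="demo",
                            canonical=ALPRAZOLAM),
            LocalConceptMap(local_code="GLU", local_vocabulary="demo-lab",
                            canonical=SERUM_GLUCOSE),
            LocalConceptMap(local_code="K", local_vocabulary="demo-lab",
                            canonical=POTASSIUM),
        ],
        unit_conversions=[
            UnitConversion(from_unit="mcg", to_unit="mg", factor=0.001),
            UnitConversion(from_unit="mg", to_unit="mcg", factor=1000.0),
            UnitConversion(from_unit="g", to_unit="mg", factor=1000.0),
            UnitConversion(from_unit="mg", to_unit="g", factor=0.001),
        ],
    )
    kb.validate_integrity()
    return kb


class FixtureSpec(BaseModel):
    """Parameters of the synthetic ward population.

    Defaults emulate a polypharmacy internal-medicine ward: ages centred
    in the mid-80s and roughly 8–20 concurrent medications per patient.
    """

    seed: int = 0
    n_patients: int = Field(default=20, gt=0)
    age_range: tuple[int, int] = (66, 95)
    orders_per_patient: tuple[int, int] = (8, 20)
    fraction_prn: float = Field(default=0.15, ge=0, le=1)
    fraction_dbi_drugs: float = Field(default=0.3, ge=0, le=1)
    fraction_trigger_drugs: float = Field(default=0.2, ge=0, le=1)
    lab_abnormal_rate: float = Field(default=0.3, ge=0, le=1)

    @model_validator(mode="after")
    def _intervals(self) -> "FixtureSpec":
        for name in ("age_range", "orders_per_patient"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is empty")
        return self


_BASE_TS = _dt.datetime(2022, 7, 1, 8, 0, tzinfo=_dt.timezone.utc)


def generate_cases(spec: FixtureSpec, kb: KnowledgeBase) -> list[PatientCase]:
    """Seeded synthetic patient cases drawn from the KB's own concepts.

    Every generated order uses a form/route and frequency that carry KB
    weights, so cases evaluate without knowledge-gap records. Burden-list
    drugs are dosed at, below or above their minimum effective daily dose;
    trigger drugs come with a matching laboratory result that is abnormal
    at the configured rate.
    """
    rng = random.Random(spec.seed)
    forms = list(kb.form_route_weights)
    freqs = list(kb.frequency_weights)
    # keep the burden construction guarantee exact: trigger-branch drugs
    # must not also sit on the burden list
    dbi_ingredients = {e.ingredient.id for e in kb.dbi_entries}
    trigger_pool = [e for e in kb.trigger_entries if e.ingredient.id not in dbi_ingredients]
    cases: list[PatientCase] = []

    for p in range(spec.n_patients):
        pid = f"synth-{spec.seed}-{p:03d}"
        age = rng.randint(*spec.age_range)
        n_orders = rng.randint(*spec.orders_per_patient)
        orders: list[MedicationOrder] = []
        labs: list[LabResult] = []

        for i in range(n_orders):
            oid = f"{pid}-o{i:02d}"
            prn = rng.random() < spec.fraction_prn
            freq = rng.choice(freqs)
            u = rng.random()
            if u < spec.fraction_dbi_drugs and kb.dbi_entries:
                entry = rng.choice(kb.dbi_entries)
                # single-administration dose putting the daily dose at
                # 0.5x, 1x or 2x the minimum effective daily dose
                mult = rng.choice([0.5, 1.0, 2.0])
                per_admin = entry.min_effective_daily_dose * mult / freq.times_per_day
                dose_unit = entry.dose_unit
                if rng.random() < 0.25:  # exercise unit conversion
                    per_admin *= 1000.0
                    dose_unit = "mcg"
                orders.append(MedicationOrder(
                    order_id=oid, vmp=DEMO_VMP_SEDANOL, ingredient=entry.ingredient,
                    form_route=ORAL_TABLET, dose=per_admin, dose_unit=dose_unit,
                    frequency=freq.concept, prn=prn, route=entry.route))
            elif u < spec.fraction_dbi_drugs + spec.fraction_trigger_drugs and trigger_pool:
                entry = rng.choice(trigger_pool)
                route = entry.route if entry.route != "*" else "oral"
                orders.append(MedicationOrder(
                    order_id=oid, vmp=DEMO_VMP_PLAINOL, ingredient=entry.ingredient,
                    form_route=rng.choice(forms).concept, dose=rng.choice([10.0, 20.0, 40.0]),
                    dose_unit="mg", frequency=freq.concept, prn=prn, route=route))
                abnormal = rng.random() < spec.lab_abnormal_rate
                span = entry.high - entry.low
                if abnormal:
                    go_low = entry.low > 0 and rng.random() < 0.5
                    if go_low:
                        value = entry.low - (0.1 + rng.random()) * max(span, 1.0) * 0.05
                    else:
                        value = entry.high + (0.1 + rng.random()) * max(span, 1.0) * 0.2
                else:
                    value = entry.low + rng.random() * span
                labs.append(LabResult(
                    test=entry.lab_test, value=round(value, 2), unit=entry.lab_unit,
                    observed_at=_BASE_TS + _dt.timedelta(hours=rng.randint(0, 72))))
            else:
                orders.append(MedicationOrder(
                    order_id=oid, vmp=DEMO_VMP_PLAINOL, ingredient=DEMO_PLAINOL,
                    form_route=rng.choice(forms).concept, dose=rng.choice([5.0, 10.0, 25.0]),
                    dose_unit="mg", frequency=freq.concept, prn=prn, route="oral"))

        cases.append(PatientCase(patient_id=pid, age_years=age, orders=orders, labs=labs))
    return cases
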