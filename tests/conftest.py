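"""Shared fixtures and independent brute-force oracles.

The oracles recompute every score straight from the definitions —
dictionary lookups and explicit sums over the orders — without touching
the scoring modules, so implementation and oracle can only agree by
computing the same quantity.
"""

from __future__ import annotations

import datetime as dt

import pytest

from medscreen import (
    ConceptRef,
    KnowledgeBase,
    LabResult,
    MedicationOrder,
    PatientCase,
    build_demo_kb,
)
from medscreen.demo import ONCE_DAILY, ORAL_TABLET

UTC = dt.timezone.utc


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return build_demo_kb()


def make_order(order_id="o1", *, ingredient=None, form_route=None, frequency=None,
               dose=10.0, dose_unit="mg", prn=False, route="oral", vmp=None) -> MedicationOrder:
    generic = ConceptRef(id="demo:ing/plainol", label="Plainol (demo, burden-free)")
    return MedicationOrder(
        order_id=order_id,
        vmp=vmp or ConceptRef(id="demo:vmp/plainol-10mg-tablet", label="Plainol 10mg tablet (demo)"),
        ingredient=ingredient or generic,
        form_route=form_route or ORAL_TABLET,
        dose=dose,
        dose_unit=dose_unit,
        frequency=frequency or ONCE_DAILY,
        prn=prn,
        route=route,
    )


def make_case(orders, labs=(), age=83, patient_id="p1") -> PatientCase:
    return PatientCase(patient_id=patient_id, age_years=age,
                       orders=list(orders), labs=list(labs))


def lab(test: ConceptRef, value: float, unit: str, hours: float = 0) -> LabResult:
    return LabResult(test=test, value=value, unit=unit,
                     observed_at=dt.datetime(2022, 7, 2, 8, 0, tzinfo=UTC) + dt.timedelta(hours=hours))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_mrci(case: PatientCase, kb: KnowledgeBase, include_prn: bool = False):
    """(A, B, C, total) recomputed from first principles."""
    active = [o for o in case.orders if include_prn or not o.prn]
    a_weights = {w.concept.id: w.weight_a for w in kb.form_route_weights}
    b = {w.concept.id: w for w in kb.frequency_weights}
    c_weights = {w.vmp.id: w.weight_c for w in kb.product_instruction_weights}
    a = sum(a_weights[fid] for fid in {o.form_route.id for o in active})
    b_score = sum(
        (b[o.frequency.id].weight_b_prn if o.prn else b[o.frequency.id].weight_b_scheduled)
        for o in active)
    c = sum(c_weights.get(o.vmp.id, 0.0) for o in active)
    return a, b_score, c, a + b_score + c


def oracle_dbi(case: PatientCase, kb: KnowledgeBase, include_prn: bool = False) -> float:
    """Σ D/(δ+D) recomputed directly over the orders."""
    tpd = {w.concept.id: w.times_per_day for w in kb.frequency_weights}
    total = 0.0
    for o in case.orders:
        if o.prn and not include_prn:
            continue
        matches = [e for e in kb.dbi_entries
                   if e.ingredient.id == o.ingredient.id and e.route == o.route
                   and e.age_min_years <= case.age_years <= e.age_max_years]
        if not matches:
            continue
        entry = min(matches, key=lambda e: (e.age_max_years - e.age_min_years,
                                            e.min_effective_daily_dose))
        factor = kb.conversion_factor(o.dose_unit, entry.dose_unit)
        d = o.dose * tpd[o.frequency.id] * factor * entry.base_period_hours / 24.0
        total += d / (entry.min_effective_daily_dose + d)
    return total


def oracle_triggers(case: PatientCase, kb: KnowledgeBase, include_prn: bool = False):
    """Set of (entry index, direction) over the full cross product of
    orders × trigger entries × labs."""
    fired = {}
    for idx, entry in enumerate(kb.trigger_entries):
        for o in case.orders:
            if o.prn and not include_prn:
                continue
            if entry.ingredient.id != o.ingredient.id:
                continue
            if entry.route not in ("", "*") and entry.route != o.route:
                continue
            if not (entry.age_min_years <= case.age_years <= entry.age_max_years):
                continue
            latest = None
            for l in case.labs:
                if l.test.id == entry.lab_test.id and (latest is None or l.observed_at >= latest.observed_at):
                    latest = l
            if latest is None:
                continue
            if latest.unit.strip().lower() != entry.lab_unit.strip().lower():
                continue
            if latest.value < entry.low:
                fired[idx] = "below_low"
            elif latest.value > entry.high:
                fired[idx] = "above_high"
    return set(fired.items())
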