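"""Adverse-drug-event trigger screening on laboratory values.

A trigger pairs a high-alert ingredient with a laboratory test and its
in-range interval; an out-of-range value in a patient taking that drug
flags a possible adverse drug event (e.g. potassium below 2.9 mEq/L
under a loop diuretic). Screening considers the ingredient regardless of
the dose, uses only the most recent value of each test, and reads the
range strictly: values exactly on a bound are in range.
"""

from __future__ import annotations

import datetime as _dt
from typing import Literal

from pydantic import BaseModel

from .kb import ConceptRef, KnowledgeBase, TriggerEntry, normalize_unit
from .patient import LabResult, PatientCase
from .trace import Trace


class TriggerHit(BaseModel):
    """One fired trigger: the rule, the order that armed it, and the
    observed out-of-range laboratory value."""

    entry: TriggerEntry
    order_id: str
    observed_value: float
    observed_unit: str
    observed_at: _dt.datetime
    direction: Literal["below_low", "above_high"]


def latest_lab(labs: list[LabResult], test: ConceptRef | str) -> LabResult | None:
    """Most recent result for a test, or ``None``.

    Ties on the timestamp are broken by document order, last wins.
    """
    test_id = test if isinstance(test, str) else test.id
    best: LabResult | None = None
    for lab in labs:
        if lab.test.id != test_id:
            continue
        if best is None or lab.observed_at >= best.observed_at:
            best = lab
    return best


def screen_triggers(case: PatientCase, kb: KnowledgeBase,
                    include_prn: bool = False, *,
                    trace: Trace | None = None) -> list[TriggerHit]:
    """All trigger hits for the case.

    For each non-PRN order and each trigger entry matching its
    ingredient, route (entries may declare a wildcard route) and the
    patient's age, the latest result of the entry's lab test is compared
    with [low, high]; a hit fires iff the value is strictly outside.
    A missing lab or a unit mismatch produces no hit but is recorded in
    the trace. At most one hit is emitted per entry, however many orders
    share the ingredient.
    """
    hits: list[TriggerHit] = []
    seen_entries: set[int] = set()
    for o in case.orders:
        if o.prn and not include_prn:
            continue
        for idx, entry in enumerate(kb.trigger_entries):
            if entry.ingredient.id != o.ingredient.id:
                continue
            if not entry.matches_route(o.route) or not entry.matches_age(case.age_years):
                continue
            if idx in seen_entries:
                continue
            lab = latest_lab(case.labs, entry.lab_test)
            if lab is None:
                if trace is not None:
                    trace.add("triggers.screen", "no_lab_value",
                              order_id=o.order_id, lab_test=entry.lab_test.id)
                continue
            if normalize_unit(lab.unit) != normalize_unit(entry.lab_unit):
                if trace is not None:
                    trace.add("triggers.screen", "unit_mismatch",
                              order_id=o.order_id, lab_test=entry.lab_test.id,
                              observed_unit=lab.unit, expected_unit=entry.lab_unit)
                continue
            if lab.value < entry.low:
                direction = "below_low"
            elif lab.value > entry.high:
                direction = "above_high"
            else:
                continue
            seen_entries.add(idx)
            hits.append(TriggerHit(entry=entry, order_id=o.order_id,
                                   observed_value=lab.value, observed_unit=lab.unit,
                                   observed_at=lab.observed_at, direction=direction))
    return hits
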