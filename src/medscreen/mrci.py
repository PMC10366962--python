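"""Medication Regimen Complexity Index (MRCI).

The index sums three sections:

* **Section A** — weights of the dosage-form / administration-route
  combinations present in the regimen. Each distinct combination is
  counted once, however many orders share it: a regimen of three oral
  tablets scores 1, not 3, because repeating an already-mastered form
  adds little complexity.
* **Section B** — a per-order weight for the dosing frequency, with
  once-daily scheduled dosing as the baseline weight of 1. Frequency
  qualifiers that the original instrument scores under section C
  (specific times, relation to meals, less-often-than-daily schedules)
  are folded into the frequency concept's B weight.
* **Section C** — a per-order weight for additional administration
  instructions attached to the virtual medicinal product; products with
  no entry contribute 0.

"As needed" (PRN) orders are excluded from all sections by default,
before any counting — including section A's distinct-form set.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .errors import KnowledgeGapError
from .kb import ConceptRef, KnowledgeBase
from .patient import MedicationOrder, PatientCase
from .trace import Trace


class MRCIScore(BaseModel):
    """Section scores, their total, and the distinct form/route concepts
    that section A counted."""

    section_a: float = Field(ge=0)
    section_b: float = Field(ge=0)
    section_c: float = Field(ge=0)
    total: float = Field(ge=0)
    counted_form_routes: list[ConceptRef] = Field(default_factory=list)


def _active(orders: list[MedicationOrder], include_prn: bool) -> list[MedicationOrder]:
    return [o for o in orders if include_prn or not o.prn]


def score_section_a(orders: list[MedicationOrder], kb: KnowledgeBase,
                    include_prn: bool = False, *,
                    trace: Trace | None = None) -> tuple[float, list[ConceptRef]]:
    """Sum of weights over the DISTINCT form/route combinations in use.

    A missing section-A weight is a knowledge gap (every prescribable
    combination must be weighted): raised, or recorded and skipped when a
    ``trace`` collector is supplied.
    """
    counted: dict[str, ConceptRef] = {}
    order_of: dict[str, str] = {}
    for o in _active(orders, include_prn):
        if o.form_route.id not in counted:
            counted[o.form_route.id] = o.form_route
            order_of[o.form_route.id] = o.order_id
    score = 0.0
    kept: list[ConceptRef] = []
    for cid, ref in counted.items():
        w = kb.form_route_weight(cid)
        if w is None:
            if trace is None:
                raise KnowledgeGapError("form/route weight", cid)
            trace.add("mrci.section_a", "knowledge_gap", concept=cid, order_id=order_of[cid])
            continue
        score += w.weight_a
        kept.append(ref)
    return score, kept


def score_section_b(orders: list[MedicationOrder], kb: KnowledgeBase,
                    include_prn: bool = False, *,
                    trace: Trace | None = None) -> float:
    """Per-order sum of frequency weights (PRN weight for PRN orders when
    they are included at all)."""
    score = 0.0
    for o in _active(orders, include_prn):
        w = kb.frequency_weight(o.frequency.id)
        if w is None:
            if trace is None:
                raise KnowledgeGapError("frequency weight", o.frequency.id)
            trace.add("mrci.section_b", "knowledge_gap", concept=o.frequency.id, order_id=o.order_id)
            continue
        score += w.weight_b_prn if o.prn else w.weight_b_scheduled
    return score


def score_section_c(orders: list[MedicationOrder], kb: KnowledgeBase,
                    include_prn: bool = False, *,
                    trace: Trace | None = None) -> float:
    """Per-order sum of product instruction weights; unlike section A this
    is per order, so duplicate products each contribute."""
    score = 0.0
    for o in _active(orders, include_prn):
        w = kb.instruction_weight(o.vmp.id)
        if w is not None:
            score += w.weight_c
    return score


def score_mrci(case: PatientCase, kb: KnowledgeBase, include_prn: bool = False, *,
               trace: Trace | None = None) -> MRCIScore:
    """Total regimen complexity: section A + section B + section C."""
    a, counted = score_section_a(case.orders, kb, include_prn, trace=trace)
    b = score_section_b(case.orders, kb, include_prn, trace=trace)
    c = score_section_c(case.orders, kb, include_prn, trace=trace)
    return MRCIScore(section_a=a, section_b=b, section_c=c, total=a + b + c,
                     counted_form_routes=counted)
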