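"""Drug Burden Index (DBI).

Cumulative anticholinergic and sedative exposure of a regimen,

    DBI = Σ D / (δ + D)

summed over every prescribed drug on the burden list, where D is the
patient's daily dose and δ the drug's minimum effective daily dose. Each
drug's term lies in [0, 1): a drug dosed at its minimum effective daily
dose contributes exactly 0.5, and the contribution saturates towards 1
as the dose grows. The daily dose is derived from the prescribed
single-administration dose, its unit (converted to the list entry's
unit) and the frequency's administrations per day; entries whose base
period is not 24 h have D rescaled to that period.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .errors import DomainError, KnowledgeGapError, UnitConversionError
from .kb import ConceptRef, DBIEntry, KnowledgeBase
from .patient import MedicationOrder, PatientCase
from .trace import Trace


class DBITerm(BaseModel):
    """One drug's contribution D/(δ+D) to the total burden."""

    order_id: str
    ingredient: ConceptRef
    daily_dose: float = Field(gt=0)
    delta: float = Field(gt=0)
    term: float = Field(ge=0, lt=1)


class DBIScore(BaseModel):
    terms: list[DBITerm] = Field(default_factory=list)
    total: float = Field(ge=0)


def dbi_term(daily_dose: float, delta: float) -> float:
    """The exposure term D/(δ+D); strictly increasing in the dose and
    strictly decreasing in the minimum effective daily dose."""
    if daily_dose <= 0 or delta <= 0:
        raise DomainError(f"dbi_term requires positive arguments, got D={daily_dose}, delta={delta}")
    return daily_dose / (delta + daily_dose)


def daily_dose(order: MedicationOrder, kb: KnowledgeBase, target_unit: str) -> float:
    """Dose taken per 24 h, expressed in ``target_unit``.

    dose × administrations-per-day × unit-conversion factor. Raises
    :class:`KnowledgeGapError` when the frequency concept has no entry
    and :class:`UnitConversionError` when no factor links the units.
    """
    freq = kb.frequency_weight(order.frequency.id)
    if freq is None:
        raise KnowledgeGapError("frequency weight", order.frequency.id)
    factor = kb.conversion_factor(order.dose_unit, target_unit)
    if factor is None:
        raise UnitConversionError(order.dose_unit, target_unit)
    return order.dose * freq.times_per_day * factor


def match_entry(kb: KnowledgeBase, ingredient_id: str, route: str,
                age_years: int) -> DBIEntry | None:
    """Burden-list entry for (ingredient, route, age), or ``None``.

    Matching requires all three. When several entries overlap the
    narrowest age range wins; ties go to the lowest δ (the conservative
    choice — it yields the larger exposure term).
    """
    candidates = [
        e for e in kb.dbi_entries
        if e.ingredient.id == ingredient_id and e.route == route and e.matches_age(age_years)
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda e: (e.age_max_years - e.age_min_years, e.min_effective_daily_dose))
    return candidates[0]


def score_dbi(case: PatientCase, kb: KnowledgeBase, include_prn: bool = False, *,
              trace: Trace | None = None) -> DBIScore:
    """Total burden over the regimen.

    One term per non-PRN order whose (ingredient, route, age) matches a
    burden-list entry; unmatched orders contribute nothing. An order
    whose ingredient is listed but only under other routes is treated as
    unmatched and noted in the trace. Unit-conversion failures are
    raised, or recorded (and the order skipped) when a ``trace``
    collector is supplied.
    """
    terms: list[DBITerm] = []
    for o in case.orders:
        if o.prn and not include_prn:
            continue
        entry = match_entry(kb, o.ingredient.id, o.route, case.age_years)
        if entry is None:
            if trace is not None and any(
                    e.ingredient.id == o.ingredient.id and e.matches_age(case.age_years)
                    for e in kb.dbi_entries):
                trace.add("dbi.match", "route_not_listed",
                          order_id=o.order_id, ingredient=o.ingredient.id, route=o.route)
            continue
        try:
            per_24h = daily_dose(o, kb, entry.dose_unit)
        except (KnowledgeGapError, UnitConversionError) as exc:
            if trace is None:
                raise
            trace.add("dbi.daily_dose", "skipped", order_id=o.order_id, reason=str(exc))
            continue
        # δ is defined per the entry's base period (normally 24 h)
        d = per_24h * entry.base_period_hours / 24.0
        terms.append(DBITerm(order_id=o.order_id, ingredient=o.ingredient,
                             daily_dose=d, delta=entry.min_effective_daily_dose,
                             term=dbi_term(d, entry.min_effective_daily_dose)))
    return DBIScore(terms=terms, total=sum(t.term for t in terms))
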