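"""Drug-burden scoring: the exposure formula, dose derivation, matching."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medscreen import DBIEntry, daily_dose, dbi_term, score_dbi
from medscreen.demo import ALPRAZOLAM, DEMO_SEDANOL, DEMO_TWICE_DAILY, ONCE_DAILY
from medscreen.dbi import match_entry
from medscreen.errors import DomainError, KnowledgeGapError, UnitConversionError
from medscreen.kb import ConceptRef
from medscreen.trace import Trace

from conftest import make_case, make_order, oracle_dbi


class TestTerm:
    def test_dose_at_minimum_effective_daily_dose_gives_half(self):
        assert dbi_term(0.5, 0.5) == 0.5
        assert dbi_term(7.3, 7.3) == 0.5

    def test_alprazolam_exemplar(self):
        """1 mg daily against the 0.5 mg minimum effective dose: 2/3."""
        assert dbi_term(1.0, 0.5) == pytest.approx(2.0 / 3.0)

    def test_vanishes_with_the_dose(self):
        assert dbi_term(1e-12, 0.5) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d,delta", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_nonpositive_arguments_rejected(self, d, delta):
        with pytest.raises(DomainError):
            dbi_term(d, delta)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(1.001, 10))
    def test_monotone_in_dose_and_antitone_in_delta(self, d, delta, factor):
        term = dbi_term(d, delta)
        assert 0 < term < 1
        assert dbi_term(d * factor, delta) > term
        assert dbi_term(d, delta * factor) < term


class TestDailyDose:
    def test_twice_daily_multiplies(self, kb):
        order = make_order(dose=0.25, dose_unit="mg", frequency=DEMO_TWICE_DAILY)
        assert daily_dose(order, kb, "mg") == pytest.approx(0.5)

    def test_microgram_prescription_converts(self, kb):
        order = make_order(dose=500, dose_unit="mcg", frequency=ONCE_DAILY)
        assert daily_dose(order, kb, "mg") == pytest.approx(0.5)

    def test_unknown_unit_pair_raises(self, kb):
        order = make_order(dose=5, dose_unit="mL")
        with pytest.raises(UnitConversionError, match="mL"):
            daily_dose(order, kb, "mg")

    def test_unknown_frequency_is_a_knowledge_gap(self, kb):
        order = make_order(frequency=ConceptRef(id="freq:unknown", label="?"))
        with pytest.raises(KnowledgeGapError):
            daily_dose(order, kb, "mg")


class TestMatching:
    def test_requires_ingredient_route_and_age(self, kb):
        assert match_entry(kb, ALPRAZOLAM.id, "oral", 83) is not None
        assert match_entry(kb, ALPRAZOLAM.id, "parenteral", 83) is None
        assert match_entry(kb, ALPRAZOLAM.id, "oral", 60) is None
        assert match_entry(kb, "ing:unlisted", "oral", 83) is None

    def test_narrowest_age_range_wins_then_lowest_delta(self, kb):
        kb2 = kb.model_copy(deep=True)
        base = kb2.dbi_entries[0]
        narrow = base.model_copy(update={"age_min_years": 80, "age_max_years": 90,
                                         "min_effective_daily_dose": 1.0})
        tied = base.model_copy(update={"age_min_years": 80, "age_max_years": 90,
                                       "min_effective_daily_dose": 0.25})
        kb2.dbi_entries += [narrow, tied]
        chosen = match_entry(kb2, base.ingredient.id, base.route, 85)
        assert (chosen.age_min_years, chosen.age_max_years) == (80, 90)
        assert chosen.min_effective_daily_dose == 0.25  # conservative: larger term


class TestScore:
    def test_no_listed_drugs_scores_zero(self, kb):
        score = score_dbi(make_case([make_order()]), kb)
        assert score.total == 0.0 and score.terms == []

    def test_single_drug_at_minimum_dose_scores_half(self, kb):
        order = make_order(ingredient=ALPRAZOLAM, dose=0.5, dose_unit="mg")
        score = score_dbi(make_case([order]), kb)
        assert score.total == 0.5
        assert score.terms[0].delta == 0.5

    def test_two_drugs_at_minimum_dose_reach_the_alert_threshold(self, kb):
        orders = [
            make_order("o1", ingredient=ALPRAZOLAM, dose=0.5, dose_unit="mg"),
            make_order("o2", ingredient=DEMO_SEDANOL, dose=10.0, dose_unit="mg"),
        ]
        assert score_dbi(make_case(orders), kb).total == pytest.approx(1.0)

    def test_prn_orders_never_contribute_by_default(self, kb):
        order = make_order(ingredient=ALPRAZOLAM, dose=5.0, dose_unit="mg", prn=True)
        assert score_dbi(make_case([order]), kb).total == 0.0
        assert score_dbi(make_case([order]), kb, include_prn=True).total > 0.0

    def test_unlisted_route_contributes_nothing_and_is_logged(self, kb):
        order = make_order(ingredient=ALPRAZOLAM, dose=1.0, dose_unit="mg",
                           route="parenteral")
        trace = Trace()
        score = score_dbi(make_case([order]), kb, trace=trace)
        assert score.total == 0.0
        assert any(r.outcome == "route_not_listed" for r in trace)

    def test_base_period_other_than_24h_rescales(self, kb):
        kb2 = kb.model_copy(deep=True)
        for e in kb2.dbi_entries:
            if e.ingredient.id == ALPRAZOLAM.id:
                e.base_period_hours = 12
        order = make_order(ingredient=ALPRAZOLAM, dose=1.0, dose_unit="mg")
        # 1 mg per 24 h is 0.5 mg per the 12 h base period
        assert score_dbi(make_case([order]), kb2).terms[0].daily_dose == pytest.approx(0.5)

    def test_terms_bounded_and_total_below_drug_count(self, kb):
        orders = [
            make_order("o1", ingredient=ALPRAZOLAM, dose=50.0, dose_unit="mg"),
            make_order("o2", ingredient=DEMO_SEDANOL, dose=900.0, dose_unit="mg"),
        ]
        score = score_dbi(make_case(orders), kb)
        assert all(0 <= t.term < 1 for t in score.terms)
        assert score.total < len(score.terms)

    def test_monotone_in_any_single_dose(self, kb):
        low = make_case([make_order(ingredient=ALPRAZOLAM, dose=0.3, dose_unit="mg")])
        high = make_case([make_order(ingredient=ALPRAZOLAM, dose=0.6, dose_unit="mg")])
        assert score_dbi(high, kb).total > score_dbi(low, kb).total

    def test_matches_brute_force_oracle_on_random_regimens(self, kb):
        rng = random.Random(42)
        ingredients = [e.ingredient for e in kb.dbi_entries] + \
            [ConceptRef(id="demo:ing/plainol", label="Plainol (demo, burden-free)")]
        freqs = [w.concept for w in kb.frequency_weights]
        for _ in range(200):
            orders = [
                make_order(f"o{i}", ingredient=rng.choice(ingredients),
                           frequency=rng.choice(freqs),
                           dose=rng.choice([0.25, 0.5, 1.0, 10.0, 500.0]),
                           dose_unit=rng.choice(["mg", "mcg"]),
                           prn=rng.random() < 0.3,
                           route=rng.choice(["oral", "parenteral"]))
                for i in range(rng.randint(0, 8))
            ]
            case = make_case(orders, age=rng.randint(60, 99))
            include_prn = rng.random() < 0.5
            assert score_dbi(case, kb, include_prn).total == pytest.approx(
                oracle_dbi(case, kb, include_prn))
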