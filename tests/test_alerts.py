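"""Alerting rules, thresholds, soft-stop suppression and summaries."""

import pytest

from medscreen import (
    SuppressionRegistry,
    color_for,
    evaluate,
    is_eligible,
    record_response,
    summarize,
)
from medscreen.alerts import REVIEW_TOTAL_TREATMENT
from medscreen.demo import ALPRAZOLAM, DEMO_SEDANOL, FUROSEMIDE, SERUM_GLUCOSE
from medscreen.errors import DomainError

from conftest import lab, make_case, make_order


def _high_dbi_case(patient_id="p1", age=83):
    """Two burden-listed drugs, each at its minimum effective daily dose:
    two terms of 0.5 summing exactly to the alert threshold."""
    return make_case(
        [make_order("o1", ingredient=ALPRAZOLAM, dose=0.5, dose_unit="mg"),
         make_order("o2", ingredient=DEMO_SEDANOL, dose=10.0, dose_unit="mg")],
        age=age, patient_id=patient_id)


def _mrci_case_with_total(kb, target: float, **kw):
    """Regimen whose complexity total is exactly ``target``: one oral
    tablet (A=1) plus once-daily orders (B=1 each)."""
    n_orders = int(target) - 1
    return make_case([make_order(f"o{i}") for i in range(n_orders)], **kw)


class TestEligibility:
    @pytest.mark.parametrize("age,expected", [(80, True), (65, True), (64, False)])
    def test_age_gate_is_inclusive_at_the_minimum(self, kb, age, expected):
        assert is_eligible(make_case([], age=age), kb) is expected

    def test_configurable_minimum_age(self, kb):
        kb2 = kb.model_copy(deep=True)
        kb2.thresholds.min_age_years = 70
        assert not is_eligible(make_case([], age=65), kb2)

    def test_ineligible_patient_gets_scores_but_no_alerts(self, kb):
        """Scores are computed and traced even below the age gate; note the
        burden is 0 here because burden-list entries are themselves
        age-ranged from 65."""
        case = _mrci_case_with_total(kb, 40.0)
        case.age_years = 64
        result = evaluate(case, kb)
        assert result.mrci.total == 40.0
        assert result.alerts == []
        assert any(r.outcome == "ineligible" for r in result.trace)

    def test_burden_entries_age_range_gates_matching(self, kb):
        assert evaluate(_high_dbi_case(age=64), kb).dbi.total == 0.0


class TestColors:
    @pytest.mark.parametrize("level,color", [
        ("contraindicated", "red"), ("moderate", "orange"),
        ("low", "yellow"), ("risk_minimization", "blue")])
    def test_level_color_mapping(self, level, color):
        assert color_for(level) == color

    def test_unknown_level_is_a_domain_error(self):
        with pytest.raises(DomainError):
            color_for("catastrophic")


class TestThresholds:
    def test_complexity_alert_fires_at_exactly_40(self, kb):
        result = evaluate(_mrci_case_with_total(kb, 40.0), kb)
        assert result.mrci.total == 40.0
        assert [a.use_case for a in result.alerts] == ["mrci"]

    def test_complexity_alert_silent_just_below_40(self, kb):
        case = _mrci_case_with_total(kb, 40.0)
        kb2 = kb.model_copy(deep=True)
        kb2.thresholds.mrci_alert = 40.0
        # shave the last order off: total 39 < 40
        case.orders.pop()
        result = evaluate(case, kb2)
        assert result.mrci.total == 39.0
        assert result.alerts == []

    def test_burden_alert_fires_at_exactly_one(self, kb):
        result = evaluate(_high_dbi_case(), kb)
        assert result.dbi.total == pytest.approx(1.0)
        dbi_alerts = [a for a in result.alerts if a.use_case == "dbi"]
        assert len(dbi_alerts) == 1
        assert {t.id for t in dbi_alerts[0].targets} == {ALPRAZOLAM.id, DEMO_SEDANOL.id}

    def test_burden_alert_silent_just_below_one(self, kb):
        case = make_case(
            [make_order("o1", ingredient=ALPRAZOLAM, dose=0.499, dose_unit="mg"),
             make_order("o2", ingredient=DEMO_SEDANOL, dose=10.0, dose_unit="mg")])
        result = evaluate(case, kb)
        assert result.dbi.total < 1.0
        assert [a.use_case for a in result.alerts] == []

    def test_crossing_a_threshold_flips_exactly_that_alert(self, kb):
        """Threshold sharpness: adding the dose that crosses the burden
        cut-off adds the burden alert and nothing else."""
        below = evaluate(make_case(
            [make_order("o1", ingredient=ALPRAZOLAM, dose=0.4, dose_unit="mg")]), kb)
        above = evaluate(_high_dbi_case(), kb)
        assert [a.use_case for a in below.alerts] == []
        assert [a.use_case for a in above.alerts] == ["dbi"]


class TestAlertShape:
    def test_complexity_alert_is_global_with_sentinel_target(self, kb):
        result = evaluate(_mrci_case_with_total(kb, 40.0), kb)
        alert = result.alerts[0]
        assert alert.template.intervention == "global_drug"
        assert alert.targets == [REVIEW_TOTAL_TREATMENT]
        assert alert.display_color == "blue"

    def test_trigger_alert_names_the_drug(self, kb):
        case = make_case([make_order("o1", ingredient=FUROSEMIDE, route="parenteral")],
                         [lab(SERUM_GLUCOSE, 130.0, "mg/dL")])
        result = evaluate(case, kb)
        trig = [a for a in result.alerts if a.use_case == "trigger"]
        assert len(trig) == 1
        assert trig[0].targets[0].id == FUROSEMIDE.id
        assert trig[0].display_color == "yellow"

    def test_alert_ids_are_deterministic_across_evaluations(self, kb):
        a = evaluate(_high_dbi_case(), kb).alerts[0].alert_id
        b = evaluate(_high_dbi_case(), kb).alerts[0].alert_id
        assert a == b

    def test_every_alert_is_traceable(self, kb):
        case = _high_dbi_case()
        case.orders += _mrci_case_with_total(kb, 40.0).orders
        result = evaluate(case, kb)
        emitted_in_trace = {r.detail.get("alert_id") for r in result.trace
                            if r.outcome == "emitted"}
        assert {a.alert_id for a in result.alerts} == emitted_in_trace


class TestSuppression:
    def test_ignore_once_suppresses_on_reevaluation(self, kb):
        registry = SuppressionRegistry()
        case = _high_dbi_case()
        first = evaluate(case, kb, registry)
        aid = first.alerts[0].alert_id
        record_response(registry, case.patient_id, aid, "ignored")
        second = evaluate(case, kb, registry)
        assert second.alerts == []
        assert second.suppressed == [aid]

    def test_accepted_alerts_reappear_while_the_condition_persists(self, kb):
        registry = SuppressionRegistry()
        case = _high_dbi_case()
        aid = evaluate(case, kb, registry).alerts[0].alert_id
        record_response(registry, case.patient_id, aid, "accepted")
        second = evaluate(case, kb, registry)
        assert [a.alert_id for a in second.alerts] == [aid]

    def test_suppression_is_per_use_case_and_target(self, kb):
        registry = SuppressionRegistry()
        case = _high_dbi_case()
        case.orders += _mrci_case_with_total(kb, 40.0).orders
        first = evaluate(case, kb, registry)
        assert len(first.alerts) == 2
        dbi_id = next(a.alert_id for a in first.alerts if a.use_case == "dbi")
        record_response(registry, case.patient_id, dbi_id, "ignored")
        second = evaluate(case, kb, registry)
        assert [a.use_case for a in second.alerts] == ["mrci"]
        assert second.suppressed == [dbi_id]

    def test_double_ignore_is_idempotent(self, kb):
        registry = SuppressionRegistry()
        case = _high_dbi_case()
        aid = evaluate(case, kb, registry).alerts[0].alert_id
        record_response(registry, case.patient_id, aid, "ignored")
        record_response(registry, case.patient_id, aid, "ignored")
        assert len(registry.ignored[case.patient_id]) == 1

    def test_unknown_alert_id_is_a_domain_error(self, kb):
        registry = SuppressionRegistry()
        evaluate(_high_dbi_case(), kb, registry)
        with pytest.raises(DomainError):
            record_response(registry, "p1", "feedfacedeadbeef", "ignored")

    def test_registry_persists_through_json(self, kb, tmp_path):
        registry = SuppressionRegistry()
        case = _high_dbi_case()
        aid = evaluate(case, kb, registry).alerts[0].alert_id
        record_response(registry, case.patient_id, aid, "ignored")
        registry.save(tmp_path / "reg.json")
        reloaded = SuppressionRegistry.load(tmp_path / "reg.json")
        assert evaluate(case, kb, reloaded).suppressed == [aid]


class TestSummarize:
    def test_empty_input_gives_all_zero_table(self):
        table = summarize([])
        assert (table[["emitted", "suppressed", "accepted", "ignored"]].to_numpy() == 0).all()

    def test_counts_match_a_hand_count(self, kb):
        registry = SuppressionRegistry()
        results = []
        for i in range(4):
            case = _high_dbi_case(patient_id=f"p{i}")
            if i < 2:
                case.orders += _mrci_case_with_total(kb, 40.0).orders
            results.append(evaluate(case, kb, registry))
        record_response(registry, "p0", results[0].alerts[0].alert_id, "accepted")
        table = summarize(results, registry)
        assert table.loc["dbi", "emitted"] == 4
        assert table.loc["mrci", "emitted"] == 2
        assert table.loc["trigger", "emitted"] == 0
        assert table.loc["dbi", "share_pct"] == pytest.approx(100 * 4 / 6)

    def test_shares_sum_to_one_hundred(self, kb):
        results = [evaluate(_high_dbi_case(patient_id=f"p{i}"), kb) for i in range(3)]
        assert summarize(results)["share_pct"].sum() == pytest.approx(100.0)
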