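"""Activity budgets, the SMS scheduler, TIA triggers, pre/post deltas."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from chimpwelfare.budgets import (
    TimeBudget,
    all_occurrence_rates,
    assign_observation_slots,
    budget_from_focal,
    budget_from_scans,
    evaluate_tia_triggers,
    pre_post_comparison,
    sms_reasons,
    sms_schedule,
    tia_observation_plan,
)
from chimpwelfare.core import BehaviorReport, ObservationRecord
from chimpwelfare.wounds import ConcernFlag

T0 = dt.datetime(2022, 1, 1, 8, 0)


def scan(code, chimp="Kasey", minute=0):
    return ObservationRecord(T0 + dt.timedelta(minutes=minute), "o", chimp,
                             code, "instantaneous")


def focal(code, seconds, chimp="Kasey", offset_s=0):
    return ObservationRecord(T0 + dt.timedelta(seconds=offset_s), "o", chimp,
                             code, "continuous", duration_s=float(seconds))


def make_budget(abnormal_pct, subject="Kasey"):
    rest = 100.0 - abnormal_pct
    pct = {c: 0.0 for c in
           ("inactive", "food_drink", "self_directed", "locomotion", "affiliative",
            "abnormal", "aggressive", "sexual", "other")}
    pct["abnormal"] = abnormal_pct
    pct["inactive"] = rest
    return TimeBudget(subject=subject, period=None, pct=pct, n_samples=100)


def test_single_category_scans_give_100_percent():
    b = budget_from_scans([scan("rest", minute=i) for i in range(5)])
    assert b.pct["inactive"] == 100.0
    assert sum(b.pct.values()) == pytest.approx(100.0)


def test_four_categories_give_25_percent_each():
    b = budget_from_scans([scan("rest"), scan("feed", minute=1),
                           scan("walk", minute=2), scan("self_groom", minute=3)])
    for cat in ("inactive", "food_drink", "locomotion", "self_directed"):
        assert b.pct[cat] == 25.0


def test_all_occurrence_records_excluded_from_scan_denominator():
    records = [scan("rest"), scan("rest", minute=1),
               ObservationRecord(T0, "o", "Kasey", "scream", "all_occurrence")]
    b = budget_from_scans(records)
    assert b.n_samples == 2


def test_budget_order_invariance_and_empty_error():
    records = [scan("rest"), scan("feed", minute=1), scan("walk", minute=2)]
    assert budget_from_scans(records).pct == budget_from_scans(records[::-1]).pct
    with pytest.raises(ValueError):
        budget_from_scans([], subject="nobody")


def test_focal_budget_fractions_by_duration():
    sessions = [focal("rest", 810), focal("wound_pick", 90, offset_s=810)]
    b = budget_from_focal(sessions, "Kasey")
    assert b.pct["abnormal"] == pytest.approx(10.0)
    assert b.pct["inactive"] == pytest.approx(90.0)
    assert b.n_samples == 900


def test_focal_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        budget_from_focal([focal("rest", 600), focal("feed", 600, offset_s=300)],
                          "Kasey")


def test_concatenated_focal_sessions_equal_duration_weighted_average():
    s1 = [focal("rest", 900)]
    s2 = [focal("wound_pick", 300, offset_s=3600)]
    combined = budget_from_focal(s1 + s2, "Kasey")
    b1, b2 = budget_from_focal(s1, "Kasey"), budget_from_focal(s2, "Kasey")
    for c in combined.pct:
        expected = (b1.pct[c] * 900 + b2.pct[c] * 300) / 1200
        assert combined.pct[c] == pytest.approx(expected)


def test_all_occurrence_rates_per_hour():
    events = [ObservationRecord(T0 + dt.timedelta(minutes=i), "o", "Kasey",
                                "scream", "all_occurrence") for i in range(3)]
    rates = all_occurrence_rates(events, observed_hours=1.5)
    assert rates["scream"] == pytest.approx(2.0)
    assert all(rates[c] == 0.0 for c in rates if c != "scream")
    # doubling events and time leaves rates unchanged
    doubled = all_occurrence_rates(events * 2, observed_hours=3.0)
    assert doubled == pytest.approx(rates)
    with pytest.raises(ValueError):
        all_occurrence_rates(events, observed_hours=0)


SMS_TABLE_EXPECTED = {
    "Post-Social Integration": (90, 13),
    "Separation from Group": (90, 13),
    "Yearly Check-In": (42, 6),
    "Wounding/Aggression/Welfare": (42, 6),
    "Considered for Integration": (42, 6),
    "Release to Novel Area": (28, 4),
    "New Arrival": (90, 13),
    "Pre-Social Integration": (42, 6),
    "Wounding/Aggression Check-In": (42, 6),
    "New Arrival 6 Month Check In": (28, 4),
    "Integration Check In 6 Months": (28, 4),
    "Integration Check-In 1 Year": (28, 4),
    "Death of a Group Member": (42, 6),
}


def test_sms_schedule_covers_exactly_the_thirteen_reasons():
    assert set(sms_reasons()) == set(SMS_TABLE_EXPECTED)
    assert len(sms_reasons()) == 13
    for reason, (days, n) in SMS_TABLE_EXPECTED.items():
        s = sms_schedule(reason)
        assert (s.duration_days, s.n_observations) == (days, n)
    with pytest.raises(KeyError, match="valid reasons"):
        sms_schedule("Vacation")


def test_observation_slots_deterministic_and_in_range():
    schedule = sms_schedule("Post-Social Integration")
    start = dt.date(2022, 5, 1)
    plan = assign_observation_slots(schedule, "Kasey", start, seed=7)
    assert plan == assign_observation_slots(schedule, "Kasey", start, seed=7)
    assert plan != assign_observation_slots(schedule, "Kasey", start, seed=8)
    assert len(plan) == 13
    for slot in plan:
        assert start <= slot["date"] <= start + dt.timedelta(days=90)
        assert (slot["block_start"], slot["block_end"]) in (
            ("07:30", "10:30"), ("10:30", "12:30"), ("13:30", "15:30"))


def test_observation_blocks_are_uniform_over_seeds():
    schedule = sms_schedule("Release to Novel Area")
    counts = {"07:30": 0, "10:30": 0, "13:30": 0}
    for seed in range(750):  # 750 seeds x 4 slots = 3000 block draws
        for slot in assign_observation_slots(schedule, "c", dt.date(2022, 1, 1), seed):
            counts[slot["block_start"]] += 1
    observed = np.array(list(counts.values()))
    p = stats.chisquare(observed).pvalue
    assert p > 0.01


def test_slots_reject_too_short_duration():
    from chimpwelfare.budgets import SMSSchedule

    with pytest.raises(ValueError):
        assign_observation_slots(SMSSchedule("x", 3, 5), "c", dt.date(2022, 1, 1), 0)


def test_tia_budget_trigger_is_strictly_above_10_percent():
    at = evaluate_tia_triggers("Kasey", budget=make_budget(10.0))
    assert at == []
    above = evaluate_tia_triggers("Kasey", budget=make_budget(10.1))
    assert [t.cause for t in above] == ["abnormal_budget_exceeds"]


def test_tia_wound_flag_trigger():
    flag = ConcernFlag("Kasey", dt.date(2022, 1, 1), dt.date(2022, 1, 14),
                       "grade5_count", 1)
    triggers = evaluate_tia_triggers("Kasey", wound_flags=[flag])
    assert [t.cause for t in triggers] == ["wound_criteria"]
    # flags for other chimps do not trigger
    assert evaluate_tia_triggers("Tessa", wound_flags=[flag]) == []


def test_tia_report_triggers_are_independent_causes():
    high = BehaviorReport("Kasey", dt.date(2022, 2, 1), "self-injury", priority="high")
    triggers = evaluate_tia_triggers("Kasey", reports=[high])
    assert [t.cause for t in triggers] == ["high_priority_report"]
    change = BehaviorReport("Kasey", dt.date(2022, 2, 2), "stopped eating",
                            priority="low", notable_change=True)
    causes = {t.cause for t in evaluate_tia_triggers("Kasey", reports=[high, change])}
    assert causes == {"high_priority_report", "notable_change_report"}


def test_pre_post_deltas_subtract_and_sum_to_zero():
    pre, post = make_budget(5.71), make_budget(0.26)
    deltas = pre_post_comparison(pre, post)
    assert deltas["abnormal"] == pytest.approx(-5.45)
    assert sum(deltas.values()) == pytest.approx(0.0, abs=1e-6)
    assert all(v == 0.0 for v in pre_post_comparison(pre, pre).values())


def test_tia_plan_covers_two_phases_of_daily_focals():
    plan = tia_observation_plan("Kasey", dt.date(2022, 5, 1))
    assert len(plan) == 28  # 14 pre + 14 post daily 15-min sessions
    assert {p["phase"] for p in plan} == {"pre_intervention", "post_intervention"}
    assert all(p["minutes"] == 15 for p in plan)
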