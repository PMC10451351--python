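"""Activity budgets, the SMS observation scheduler, and TIA triggers.

Instantaneous scan samples estimate the fraction of time spent in each
behavioral category (sample proportions are unbiased for time fractions
under instantaneous sampling); continuous focal sessions yield
duration-based budgets.  All-occurrence records capture rare events and
are reported as rates per observation hour, never entering scan
denominators.

The Social Monitoring System scheduler maps each of thirteen observation
reasons (post-integration, new arrival, yearly check-in, ...) to a fixed
(duration, observations-per-chimp) pair and spreads seeded observation
slots over three daily time blocks (07:30-10:30, 10:30-12:30,
13:30-15:30).

Targeted Individual Assessments are triggered by high-priority abnormal
behavior reports, wound concern flags, an abnormal-category budget share
strictly above 10%, or externally filed notable-change reports.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import BehaviorReport, Ethogram, ObservationRecord, default_ethogram
from .defaults import OBSERVATION_TIME_BLOCKS, SMS_SCHEDULE_TABLE
from .wounds import ConcernFlag

__all__ = [
    "TimeBudget",
    "SMSSchedule",
    "TIATrigger",
    "TIA_ABNORMAL_THRESHOLD_PCT",
    "budget_from_scans",
    "budget_from_focal",
    "all_occurrence_rates",
    "sms_schedule",
    "sms_reasons",
    "assign_observation_slots",
    "evaluate_tia_triggers",
    "pre_post_comparison",
    "tia_observation_plan",
]

TIA_ABNORMAL_THRESHOLD_PCT = 10.0


@dataclass(frozen=True)
class TimeBudget:
    subject: str  # chimp id, group id, or "colony"
    period: tuple[dt.date, dt.date] | None
    pct: dict[str, float]  # category -> percent of observation time
    n_samples: float  # scan count, or total focal seconds

    def __post_init__(self) -> None:
        total = sum(self.pct.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"budget percentages sum to {total}, not 100")


@dataclass(frozen=True)
class SMSSchedule:
    reason: str
    duration_days: int
    n_observations: int


@dataclass(frozen=True)
class TIATrigger:
    chimp_id: str
    date: dt.date
    cause: str  # high_priority_report | wound_criteria | abnormal_budget_exceeds | notable_change_report
    evidence: object = None


def _in_period(ts: dt.datetime, period: tuple[dt.date, dt.date] | None) -> bool:
    return period is None or period[0] <= ts.date() <= period[1]


def _full_pct(counts: Mapping[str, float], total: float, ethogram: Ethogram) -> dict[str, float]:
    return {c: 100.0 * counts.get(c, 0.0) / total for c in ethogram.categories}


def budget_from_scans(
    scans: Iterable[ObservationRecord],
    ethogram: Ethogram | None = None,
    subject: str | None = None,
    period: tuple[dt.date, dt.date] | None = None,
    members: Sequence[str] | None = None,
) -> TimeBudget:
    """Time budget from instantaneous scan points.

    ``subject`` restricts to one focal chimp; ``members`` restricts to a
    group (scans pooled over members); both None pools the colony.
    All-occurrence and continuous records are excluded from the
    denominator.
    """
    eth = ethogram or default_ethogram()
    counts: Counter[str] = Counter()
    n = 0
    for r in scans:
        if r.sampling != "instantaneous":
            continue
        if subject is not None and r.focal_id != subject:
            continue
        if members is not None and r.focal_id not in members:
            continue
        if not _in_period(r.timestamp, period):
            continue
        counts[eth.category_of(r.behavior_code)] += 1
        n += 1
    if n == 0:
        raise ValueError("no in-scope instantaneous scans")
    name = subject if subject is not None else ("group" if members is not None else "colony")
    return TimeBudget(subject=name, period=period, pct=_full_pct(counts, n, eth), n_samples=n)


def budget_from_focal(
    sessions: Iterable[ObservationRecord],
    chimp_id: str,
    ethogram: Ethogram | None = None,
    period: tuple[dt.date, dt.date] | None = None,
) -> TimeBudget:
    """Duration-weighted time budget from continuous focal records."""
    eth = ethogram or default_ethogram()
    seconds: Counter[str] = Counter()
    intervals: list[tuple[dt.datetime, dt.datetime]] = []
    total = 0.0
    for r in sessions:
        if r.sampling != "continuous" or r.focal_id != chimp_id:
            continue
        if not _in_period(r.timestamp, period):
            continue
        if r.duration_s is None or r.duration_s <= 0:
            raise ValueError("continuous records must carry a positive duration")
        end = r.timestamp + dt.timedelta(seconds=r.duration_s)
        for s0, e0 in intervals:
            if r.timestamp < e0 and s0 < end:
                raise ValueError(
                    f"overlapping focal intervals at {r.timestamp.isoformat()}"
                )
        intervals.append((r.timestamp, end))
        seconds[eth.category_of(r.behavior_code)] += r.duration_s
        total += r.duration_s
    if total == 0:
        raise ValueError("no in-scope focal seconds")
    return TimeBudget(subject=chimp_id, period=period,
                      pct=_full_pct(seconds, total, eth), n_samples=total)


def all_occurrence_rates(
    records: Iterable[ObservationRecord],
    observed_hours: float,
    ethogram: Ethogram | None = None,
    subject: str | None = None,
    period: tuple[dt.date, dt.date] | None = None,
) -> dict[str, float]:
    """Events per observation hour for each all-occurrence behavior."""
    if observed_hours <= 0:
        raise ValueError("observed time must be positive")
    eth = ethogram or default_ethogram()
    counts: Counter[str] = Counter()
    for r in records:
        if r.sampling != "all_occurrence":
            continue
        if subject is not None and r.focal_id != subject:
            continue
        if not _in_period(r.timestamp, period):
            continue
        counts[r.behavior_code] += 1
    return {code: counts.get(code, 0) / observed_hours for code in eth.all_occurrence}


def sms_reasons() -> tuple[str, ...]:
    return tuple(SMS_SCHEDULE_TABLE)


def sms_schedule(reason: str) -> SMSSchedule:
    """Look up the observation plan for a monitoring reason."""
    if reason not in SMS_SCHEDULE_TABLE:
        raise KeyError(
            f"unknown SMS reason {reason!r}; valid reasons: {sorted(SMS_SCHEDULE_TABLE)}"
        )
    duration, n = SMS_SCHEDULE_TABLE[reason]
    return SMSSchedule(reason=reason, duration_days=duration, n_observations=n)


def assign_observation_slots(
    schedule: SMSSchedule,
    chimp_id: str,
    start_date: dt.date,
    seed: int,
) -> list[dict]:
    """Spread seeded observation slots over the schedule's duration.

    The duration is split into ``n_observations`` equal segments; each
    slot gets a uniform random day within its segment and a uniform
    random choice among the three daily time blocks.  Deterministic
    given (schedule, chimp, start_date, seed).
    """
    n = schedule.n_observations
    if n < 1:
        raise ValueError("n_observations must be >= 1")
    if schedule.duration_days < n:
        raise ValueError(
            f"duration of {schedule.duration_days} days cannot hold {n} observation days"
        )
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, schedule.duration_days, n + 1)
    plan = []
    for i in range(n):
        lo, hi = int(np.ceil(edges[i])), int(np.ceil(edges[i + 1]))
        day = int(rng.integers(lo, max(hi, lo + 1)))
        block = OBSERVATION_TIME_BLOCKS[int(rng.integers(0, len(OBSERVATION_TIME_BLOCKS)))]
        plan.append({
            "chimp_id": chimp_id,
            "date": start_date + dt.timedelta(days=day),
            "block_start": block[0],
            "block_end": block[1],
            "reason": schedule.reason,
        })
    return plan


def evaluate_tia_triggers(
    chimp_id: str,
    reports: Sequence[BehaviorReport] = (),
    budget: TimeBudget | None = None,
    wound_flags: Sequence[ConcernFlag] = (),
    threshold_pct: float = TIA_ABNORMAL_THRESHOLD_PCT,
    as_of: dt.date | None = None,
) -> list[TIATrigger]:
    """Evaluate the four independent TIA trigger causes for one chimp.

    The budget cause fires only when the abnormal category share is
    strictly greater than ``threshold_pct`` (default 10%).
    """
    today = as_of or dt.date.today()
    triggers: list[TIATrigger] = []
    for rep in reports:
        if rep.chimp_id != chimp_id:
            continue
        if rep.priority == "high":
            triggers.append(TIATrigger(chimp_id, rep.date, "high_priority_report", rep))
        if rep.notable_change:
            triggers.append(TIATrigger(chimp_id, rep.date, "notable_change_report", rep))
    for flag in wound_flags:
        if flag.chimp_id == chimp_id:
            triggers.append(TIATrigger(chimp_id, flag.window_end, "wound_criteria", flag))
    if budget is not None and budget.subject == chimp_id:
        abnormal = budget.pct.get("abnormal", 0.0)
        if abnormal > threshold_pct:
            triggers.append(
                TIATrigger(chimp_id, budget.period[1] if budget.period else today,
                           "abnormal_budget_exceeds", budget)
            )
    return triggers


def pre_post_comparison(pre: TimeBudget, post: TimeBudget) -> dict[str, float]:
    """Per-category percentage-point change, post minus pre.

    Deltas sum to zero since both budgets are normalized to 100.
    """
    if set(pre.pct) != set(post.pct):
        raise ValueError("budgets cover different category sets")
    return {c: post.pct[c] - pre.pct[c] for c in pre.pct}


def tia_observation_plan(
    chimp_id: str,
    start: dt.date,
    phase_days: int = 14,
    sessions_per_day: int = 1,
    session_minutes: int = 15,
) -> list[dict]:
    """Template TIA schedule: daily focal sessions for a pre-intervention
    phase plus a matching during/after-intervention phase.

    Defaults encode two weeks of daily 15-minute focals per phase;
    counts are configurable since real assessments deviate in practice.
    """
    plan = []
    for phase, offset in (("pre_intervention", 0), ("post_intervention", phase_days)):
        for d in range(phase_days):
            for s in range(sessions_per_day):
                plan.append({
                    "chimp_id": chimp_id,
                    "date": start + dt.timedelta(days=offset + d),
                    "session": s + 1,
                    "minutes": session_minutes,
                    "phase": phase,
                })
    return plan
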