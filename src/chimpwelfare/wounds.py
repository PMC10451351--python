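"""Wound surveillance: grading, deduplication, rolling-window concern flags.

Wounds are graded 1 (superficial scratch) to 5 (gaping or missing body
part).  The log records only a wound's initial occurrence and any later
escalation to a strictly higher grade, so a wound_id can appear several
times; counting always deduplicates to one wound at its maximum in-window
grade.

Concern criteria are evaluated over rolling 14-day windows (both
endpoints inclusive).  Defaults: 10 wounds of any grade, 4 grade-3
wounds, 3 grade-4 wounds, or a single grade-5 wound within one window.
Grade-specific criteria count wounds of exactly that grade; higher grades
carry their own stricter criteria.  Candidate windows are anchored with
their start or their end at an event date, which is exhaustive: for any
window, sliding it so its end meets the last contained event keeps every
contained event, and the earlier events it may pick up can only add
wounds to a grade bucket, never remove them (an earlier event of an
already-counted wound has a lower grade, so in-window maxima are
unchanged).  Start-only anchoring would miss windows that end just
before an escalation moves a wound out of an exact-grade bucket.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import ChimpProfile, WoundEvent, SchemaError
from .defaults import DEFAULT_WOUND_CRITERIA

__all__ = [
    "ConcernFlag",
    "WINDOW_DAYS",
    "validate_log",
    "effective_wounds_in_window",
    "concern_flags",
    "severity_distribution",
    "wound_timeline",
]

WINDOW_DAYS = 14

_CRITERION_GRADE = {"grade3_count": 3, "grade4_count": 4, "grade5_count": 5}


@dataclass(frozen=True)
class ConcernFlag:
    chimp_id: str
    window_start: dt.date
    window_end: dt.date  # start + 13 days
    criterion: str
    count: int


def validate_log(log: Sequence[WoundEvent]) -> None:
    """Check escalation semantics: first event per wound is initial and
    each escalation strictly exceeds the wound's previous maximum grade."""
    by_wound: dict[str, list[WoundEvent]] = defaultdict(list)
    for ev in log:
        by_wound[ev.wound_id].append(ev)
    for wid, events in by_wound.items():
        events.sort(key=lambda e: e.date)
        if events[0].event_kind != "initial":
            raise SchemaError(f"wound {wid!r}: first event must be 'initial'")
        max_grade = events[0].grade
        for ev in events[1:]:
            if ev.event_kind != "escalation":
                raise SchemaError(f"wound {wid!r}: duplicate initial event")
            if ev.grade <= max_grade:
                raise SchemaError(
                    f"wound {wid!r}: escalation grade {ev.grade} does not exceed "
                    f"previous maximum {max_grade}"
                )
            max_grade = ev.grade


def effective_wounds_in_window(
    log: Iterable[WoundEvent],
    chimp_id: str,
    window_start: dt.date,
    window_end: dt.date | None = None,
) -> dict[str, int]:
    """Deduplicated wounds for one chimp in a 14-day window.

    Returns wound_id -> maximum grade among events dated inside the
    window.  The event-date filter runs before the max, so an escalation
    dated outside the window does not raise the in-window grade.
    """
    if window_end is None:
        window_end = window_start + dt.timedelta(days=WINDOW_DAYS - 1)
    wounds: dict[str, int] = {}
    for ev in log:
        if ev.chimp_id != chimp_id or not (window_start <= ev.date <= window_end):
            continue
        wounds[ev.wound_id] = max(wounds.get(ev.wound_id, 0), ev.grade)
    return wounds


def _criterion_count(wounds: Mapping[str, int], criterion: str) -> int:
    if criterion == "any_grade_total":
        return len(wounds)
    grade = _CRITERION_GRADE[criterion]
    return sum(1 for g in wounds.values() if g == grade)


def concern_flags(
    log: Sequence[WoundEvent],
    criteria: Mapping[str, int] | None = None,
) -> list[ConcernFlag]:
    """Evaluate every rolling 14-day window and emit deduplicated flags.

    For each chimp, candidate windows start at each of its event dates
    or end at one (see the module docstring for why both are needed).
    A criterion whose count meets its threshold in a window yields a
    flag; runs of overlapping satisfying windows (successive anchors less
    than 14 days apart) collapse to the earliest window of the episode,
    so one wounding episode produces one flag per criterion.
    """
    if criteria is None:
        criteria = DEFAULT_WOUND_CRITERIA
    for crit, thr in criteria.items():
        if crit not in ("any_grade_total",) and crit not in _CRITERION_GRADE:
            raise ValueError(f"unknown criterion {crit!r}")
        if not isinstance(thr, int) or thr <= 0:
            raise ValueError(f"threshold for {crit} must be a positive integer")
    validate_log(log)

    by_chimp: dict[str, list[WoundEvent]] = defaultdict(list)
    for ev in log:
        by_chimp[ev.chimp_id].append(ev)

    flags: list[ConcernFlag] = []
    for chimp_id, events in sorted(by_chimp.items()):
        anchors = sorted(
            {ev.date for ev in events}
            | {ev.date - dt.timedelta(days=WINDOW_DAYS - 1) for ev in events}
        )
        # criterion -> list of (anchor, count) for satisfying windows
        satisfied: dict[str, list[tuple[dt.date, int]]] = defaultdict(list)
        for anchor in anchors:
            wounds = effective_wounds_in_window(events, chimp_id, anchor)
            for crit, thr in criteria.items():
                count = _criterion_count(wounds, crit)
                if count >= thr:
                    satisfied[crit].append((anchor, count))
        for crit, hits in satisfied.items():
            prev: dt.date | None = None
            for anchor, count in hits:
                if prev is None or (anchor - prev).days >= WINDOW_DAYS:
                    flags.append(
                        ConcernFlag(
                            chimp_id=chimp_id,
                            window_start=anchor,
                            window_end=anchor + dt.timedelta(days=WINDOW_DAYS - 1),
                            criterion=crit,
                            count=count,
                        )
                    )
                prev = anchor
    flags.sort(key=lambda f: (f.window_start, f.chimp_id, f.criterion))
    return flags


def _effective_wounds_in_period(
    log: Iterable[WoundEvent], period: tuple[dt.date, dt.date] | None
) -> dict[str, tuple[str, dt.date, int]]:
    """wound_id -> (chimp, first in-period event date, max in-period grade)."""
    wounds: dict[str, tuple[str, dt.date, int]] = {}
    for ev in sorted(log, key=lambda e: e.date):
        if period is not None and not (period[0] <= ev.date <= period[1]):
            continue
        if ev.wound_id in wounds:
            chimp, first, grade = wounds[ev.wound_id]
            wounds[ev.wound_id] = (chimp, first, max(grade, ev.grade))
        else:
            wounds[ev.wound_id] = (ev.chimp_id, ev.date, ev.grade)
    return wounds


def severity_distribution(
    log: Sequence[WoundEvent],
    period: tuple[dt.date, dt.date] | None = None,
) -> dict[int, float]:
    """Proportion of effective (deduplicated, max-grade) wounds per grade."""
    wounds = _effective_wounds_in_period(log, period)
    if not wounds:
        raise ValueError("no effective wounds in period")
    counts = Counter(grade for _, _, grade in wounds.values())
    total = sum(counts.values())
    return {g: counts.get(g, 0) / total for g in (1, 2, 3, 4, 5) if counts.get(g)}


def wound_timeline(
    log: Sequence[WoundEvent],
    grouping: str = "colony",
    bin: str = "day",
    roster: Sequence[ChimpProfile] | None = None,
    group_id: str | None = None,
    chimp_id: str | None = None,
    period: tuple[dt.date, dt.date] | None = None,
) -> dict[str, Counter]:
    """Frequency-by-severity time series of effective wounds.

    Each deduplicated wound contributes once, in the bin of its first
    in-period event, at its maximum in-period grade; total counts over
    bins therefore equal total effective wounds.  Bins are ISO dates
    (day), ISO year-week (week), or year-month (month).
    """
    if grouping not in ("individual", "group", "colony"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if bin not in ("day", "week", "month"):
        raise ValueError(f"unknown bin {bin!r}")
    scope = None
    if grouping == "individual":
        if chimp_id is None:
            raise ValueError("individual grouping requires chimp_id")
        scope = {chimp_id}
    elif grouping == "group":
        if roster is None or group_id is None:
            raise ValueError("group grouping requires roster and group_id")
        scope = {p.chimp_id for p in roster if p.group_id == group_id}
        if not scope:
            raise ValueError(f"unknown group {group_id!r}")

    def key(d: dt.date) -> str:
        if bin == "day":
            return d.isoformat()
        if bin == "week":
            y, w, _ = d.isocalendar()
            return f"{y}-W{w:02d}"
        return f"{d.year}-{d.month:02d}"

    series: dict[str, Counter] = defaultdict(Counter)
    for chimp, first, grade in _effective_wounds_in_period(log, period).values():
        if scope is not None and chimp not in scope:
            continue
        series[key(first)][grade] += 1
    return dict(series)
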