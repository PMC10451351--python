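"""Positive-reinforcement-training analytics and shifting compliance.

Every training session is keyed by (date, time, trainer, chimp).  Cue
responses are scored on a three-point scale: 1 = seldom/never responded,
2 = needed assistance or was inconsistent, 3 = correct response the
majority of the time.

Shifting compliance for a chimp over a month is the percentage of
eligible asked-days on which it complied, where days excluded for
weather or an alternate husbandry goal leave the denominator.  Zero
eligible days yields None (undefined), which is distinct from 0%.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .core import ChimpProfile, PRTSession, ShiftRecord

__all__ = [
    "EngagementSummary",
    "session_id",
    "engagement_summary",
    "shifting_compliance",
    "group_compliance",
    "response_trend",
]


def session_id(date: dt.date, time_of_day: str, trainer: str, chimp_id: str) -> str:
    """Deterministic, injective session key from its four components."""
    parts = (date.isoformat(), time_of_day, trainer, chimp_id)
    if any(p in ("", None) for p in parts):
        raise ValueError("all four session-ID components must be present")
    # escape the separator so distinct tuples can never collide
    return "|".join(p.replace("%", "%25").replace("|", "%7C") for p in parts)


@dataclass(frozen=True)
class EngagementSummary:
    n_sessions: int
    sessions_per_month: float
    distinct_chimps: int
    colony_fraction: float  # fraction of roster with >= 1 session


def engagement_summary(
    sessions: Iterable[PRTSession],
    roster: Sequence[ChimpProfile],
    period: tuple[dt.date, dt.date],
) -> EngagementSummary:
    """Colony-level training engagement over a period."""
    if not roster:
        raise ValueError("roster must be non-empty")
    start, end = period
    in_period = [s for s in sessions if start <= s.date <= end]
    months = (end.year - start.year) * 12 + end.month - start.month + 1
    roster_ids = {p.chimp_id for p in roster}
    trained = {s.chimp_id for s in in_period} & roster_ids
    return EngagementSummary(
        n_sessions=len(in_period),
        sessions_per_month=len(in_period) / months,
        distinct_chimps=len(trained),
        colony_fraction=len(trained) / len(roster_ids),
    )


def shifting_compliance(
    records: Iterable[ShiftRecord],
    chimp_id: str,
    month: tuple[int, int] | None = None,
) -> float | None:
    """Percent of eligible asked-days the chimp complied.

    Weather-excluded days and days with an alternate goal are removed
    from the denominator; a chimp absent from a record's complied map
    was not asked that day.  Returns None when no eligible days exist.
    """
    eligible = complied = 0
    for rec in records:
        if month is not None and (rec.date.year, rec.date.month) != month:
            continue
        if rec.weather_excluded or rec.alternate_goal:
            continue
        if chimp_id not in rec.complied:
            continue
        eligible += 1
        if rec.complied[chimp_id]:
            complied += 1
    if eligible == 0:
        return None
    return 100.0 * complied / eligible


def group_compliance(
    records: Iterable[ShiftRecord],
    group_members: Sequence[str],
    month: tuple[int, int] | None = None,
    predicate: Callable[[Mapping[str, bool]], bool] | None = None,
) -> float | None:
    """Percent of eligible shifts on which the whole group complied.

    The default predicate requires every asked member to comply
    (outliers make the shift non-compliant); a custom predicate supports
    per-group alternative compliance definitions.
    """
    pred = predicate or (lambda complied: all(complied.values()))
    members = set(group_members)
    eligible = ok = 0
    for rec in records:
        if month is not None and (rec.date.year, rec.date.month) != month:
            continue
        if rec.weather_excluded or rec.alternate_goal:
            continue
        asked = {c: v for c, v in rec.complied.items() if c in members}
        if not asked:
            continue
        eligible += 1
        if pred(asked):
            ok += 1
    if eligible == 0:
        return None
    return 100.0 * ok / eligible


def response_trend(
    sessions: Iterable[PRTSession],
    chimp_id: str,
    cue: str,
) -> tuple[list[tuple[dt.date, int]], dict[tuple[int, int], float]]:
    """Chronological response scores for one cue plus per-month means."""
    scores: list[tuple[dt.date, int]] = []
    for s in sessions:
        if s.chimp_id != chimp_id:
            continue
        for c, score in s.cue_responses:
            if c == cue:
                scores.append((s.date, score))
    if not scores:
        raise KeyError(f"cue {cue!r} never recorded for {chimp_id!r}")
    scores.sort(key=lambda t: t[0])
    by_month: dict[tuple[int, int], list[int]] = {}
    for d, score in scores:
        by_month.setdefault((d.year, d.month), []).append(score)
    means = {m: sum(v) / len(v) for m, v in by_month.items()}
    return scores, means
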