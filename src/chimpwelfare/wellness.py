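"""Composite wellness scoring, action bands, and quarterly survey scheduling.

Ten behavioral parameters (abnormal behavior, locomotion, food/water
access, human-animal interaction, coat, self-aggression, social
interaction, staff concern, enrichment acceptance, wounds) are each rated
0-3 by multiple assessors drawn from the husbandry, behavior, and
veterinary teams.  Per parameter, assessor scores are averaged and
multiplied by a configurable concern weight; the weighted means are then
summed into a total on a 0-30 scale (under unit weights).  Higher totals
mean more concern.

Action bands resolve the published rule "0-12 continue quarterly
monitoring; 12-29 additional observation; >30 immediate escalation" as
half-open intervals erring toward concern: routine is [0, 12), elevated
is [12, 29], and everything above 29 is critical, so the nominally
unassigned (29, 30] range escalates rather than falling through.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import ChimpProfile, WellnessResponse
from .defaults import WELLNESS_PARAMETERS

__all__ = [
    "WellnessScore",
    "DEFAULT_WEIGHTS",
    "ROUTINE_UPPER",
    "ELEVATED_UPPER",
    "score_survey",
    "classify_wellness",
    "parameter_concern_summary",
    "schedule_wellness",
]

DEFAULT_WEIGHTS: dict[str, float] = {p: 1.0 for p in WELLNESS_PARAMETERS}

MAX_RAW_SCORE = 3

#: routine band is [0, ROUTINE_UPPER); elevated is [ROUTINE_UPPER, ELEVATED_UPPER]
ROUTINE_UPPER = 12.0
ELEVATED_UPPER = 29.0


@dataclass(frozen=True)
class WellnessScore:
    chimp_id: str
    date: dt.date
    per_parameter_mean: dict[str, float]
    total: float
    band: str


def check_weights(weights: Mapping[str, float]) -> dict[str, float]:
    missing = set(WELLNESS_PARAMETERS) - set(weights)
    if missing:
        raise ValueError(f"weights missing parameters: {sorted(missing)}")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be positive")
    attainable = MAX_RAW_SCORE * sum(weights[p] for p in WELLNESS_PARAMETERS)
    if abs(attainable - 30.0) > 1e-9:
        warnings.warn(
            f"attainable maximum wellness score is {attainable:g}, not 30; "
            "band thresholds assume the standard 0-30 scale",
            stacklevel=3,
        )
    return {p: float(weights[p]) for p in WELLNESS_PARAMETERS}


def score_survey(
    responses: Sequence[WellnessResponse],
    weights: Mapping[str, float] | None = None,
    date: dt.date | None = None,
) -> WellnessScore:
    """Aggregate one chimp/timepoint's assessor responses into a total score.

    Per parameter the assessor raw scores are averaged, then scaled by
    that parameter's weight; the total is the sum of the weighted means.
    """
    if not responses:
        raise ValueError("need at least one response")
    chimp_ids = {r.chimp_id for r in responses}
    if len(chimp_ids) > 1:
        raise ValueError(f"responses span multiple chimps: {sorted(chimp_ids)}")
    w = check_weights(DEFAULT_WEIGHTS if weights is None else weights)

    n = len(responses)
    means = {
        p: w[p] * sum(r.parameters[p] for r in responses) / n
        for p in WELLNESS_PARAMETERS
    }
    total = sum(means.values())
    return WellnessScore(
        chimp_id=responses[0].chimp_id,
        date=date or max(r.date for r in responses),
        per_parameter_mean=means,
        total=total,
        band=classify_wellness(total),
    )


def classify_wellness(total: float) -> str:
    """Map a total score to its action band: routine / elevated / critical."""
    if total < 0:
        raise ValueError(f"total score cannot be negative, got {total}")
    if total < ROUTINE_UPPER:
        return "routine"
    if total <= ELEVATED_UPPER:
        return "elevated"
    return "critical"


def parameter_concern_summary(
    scores: Iterable[WellnessScore],
    period: tuple[dt.date, dt.date],
    concern_cutoff: float = 1.0,
) -> dict[str, float]:
    """Fraction of chimps 'of concern' per parameter over a period.

    A chimp is of concern on parameter ``p`` if any of its scores in the
    period has a weighted per-parameter mean at or above ``concern_cutoff``.
    """
    start, end = period
    if end < start:
        raise ValueError("empty period")
    in_period = [s for s in scores if start <= s.date <= end]
    chimps = {s.chimp_id for s in in_period}
    out: dict[str, float] = {}
    for p in WELLNESS_PARAMETERS:
        concerned = {
            s.chimp_id
            for s in in_period
            if s.per_parameter_mean.get(p, 0.0) >= concern_cutoff
        }
        out[p] = len(concerned) / len(chimps) if chimps else 0.0
    return out


def schedule_wellness(
    roster: Sequence[ChimpProfile], year: int
) -> dict[str, list[dt.date]]:
    """Plan four surveys per chimp, one per calendar quarter.

    Surveys sit mid-quarter (Feb/May/Aug/Nov 15) so each lands in a
    different season, supporting season-by-season comparisons.
    """
    dates = [dt.date(year, m, 15) for m in (2, 5, 8, 11)]
    return {p.chimp_id: list(dates) for p in roster}
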