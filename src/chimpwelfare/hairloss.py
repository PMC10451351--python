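"""Zone-weighted hair-loss scoring, significance flagging, and scheduling.

The body is divided into seven zones (A-G), each carrying a weight equal
to its fraction of the ideal hair surface area (derivable from a grid
mask via :func:`zone_weights_from_grid`).  Observers score each zone's
hair loss on the five-point percent scale {0, 25, 50, 75, 100}; total
body hair loss is the weight-scaled sum of zone scores.  A total of 25%
or more is "significant" and escalates monitoring from the routine
15-month colony sweep to observations every 4 months by three distinct
observers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import ChimpProfile, HairLossSurvey, SchemaError
from .defaults import DEFAULT_ZONE_WEIGHTS

__all__ = [
    "ZoneMap",
    "HairLossResult",
    "SIGNIFICANT_PCT",
    "SCALE_POINTS",
    "default_zone_map",
    "zone_weights_from_grid",
    "snap_zone_score",
    "total_hair_loss",
    "flag_significant",
    "schedule_hairloss",
    "hairloss_trajectory",
]

SIGNIFICANT_PCT = 25.0
SCALE_POINTS = (0, 25, 50, 75, 100)

ROUTINE_INTERVAL_MONTHS = 15
ESCALATED_INTERVAL_MONTHS = 4
OBSERVERS_PER_ESCALATED_OCCASION = 3


@dataclass(frozen=True)
class ZoneMap:
    """Body zones with surface weights (fractions of ideal hair area)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise SchemaError("zone map must define at least one zone")
        if any(w <= 0 for w in self.weights.values()):
            raise SchemaError("zone weights must be positive")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise SchemaError(
                f"zone weights must sum to 1, got {sum(self.weights.values()):.12g}"
            )

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(self.weights)


@dataclass(frozen=True)
class HairLossResult:
    chimp_id: str
    date: dt.date
    total_pct: float
    significant: bool


def default_zone_map() -> ZoneMap:
    return ZoneMap(dict(DEFAULT_ZONE_WEIGHTS))


def zone_weights_from_grid(grid_counts: Mapping[str, int]) -> ZoneMap:
    """Derive zone weights from grid-cell counts over a body diagram.

    ``grid_counts[z]`` is the number of grid cells of the body picture
    falling in zone ``z`` (hairless parts excluded from the mask);
    weight_z = cells_z / total cells.
    """
    if not grid_counts:
        raise ValueError("grid counts must be non-empty")
    if any((not isinstance(c, int)) or c <= 0 for c in grid_counts.values()):
        raise ValueError("grid counts must be positive integers")
    total = sum(grid_counts.values())
    return ZoneMap({z: c / total for z, c in grid_counts.items()})


def snap_zone_score(observed: float) -> int:
    """Snap an observed percent to the nearest scale point.

    Exact midpoints round up, toward more loss (erring toward concern).
    """
    if not 0 <= observed <= 100:
        raise ValueError(f"score out of range: {observed}")
    best = min(SCALE_POINTS, key=lambda p: (abs(p - observed), -p))
    return best


def total_hair_loss(survey: HairLossSurvey, zone_map: ZoneMap | None = None) -> HairLossResult:
    """Weight-scaled total body hair loss percent for one survey."""
    zm = zone_map or default_zone_map()
    if set(survey.zone_scores) != set(zm.zones):
        raise SchemaError(
            f"survey zones {sorted(survey.zone_scores)} do not match "
            f"zone map {sorted(zm.zones)}"
        )
    for z, s in survey.zone_scores.items():
        if s not in SCALE_POINTS:
            raise SchemaError(f"zone {z}: score {s} not on scale {SCALE_POINTS}")
    total = sum(zm.weights[z] * survey.zone_scores[z] for z in zm.zones)
    return HairLossResult(
        chimp_id=survey.chimp_id,
        date=survey.date,
        total_pct=total,
        significant=flag_significant(total),
    )


def flag_significant(total_pct: float) -> bool:
    """True iff total body hair loss is 25% or more."""
    if not 0 <= total_pct <= 100:
        raise ValueError(f"total_pct out of range: {total_pct}")
    return total_pct >= SIGNIFICANT_PCT


def _add_months(d: dt.date, months: int) -> dt.date:
    month = d.month - 1 + months
    year = d.year + month // 12
    month = month % 12 + 1
    day = min(d.day, [31, 29 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
                      else 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return dt.date(year, month, day)


def schedule_hairloss(
    flags: Mapping[str, bool],
    roster: Sequence[ChimpProfile],
    start: dt.date,
    horizon_months: int = 15,
    new_arrivals: Sequence[str] = (),
) -> list[dict]:
    """Plan hair-loss monitoring over a horizon.

    Chimps without significant loss get one survey per 15-month cycle;
    chimps flagged significant get an occasion every 4 months, each
    staffed by three distinct observers (emitted as three planned
    observations).  New arrivals are scheduled immediately for a
    baseline survey.
    """
    plan: list[dict] = []
    for p in roster:
        if p.chimp_id in new_arrivals:
            plan.append({"chimp_id": p.chimp_id, "date": start, "observer_slot": 1,
                         "reason": "baseline_new_arrival"})
            continue
        if flags.get(p.chimp_id, False):
            occasion = _add_months(start, ESCALATED_INTERVAL_MONTHS)
            while (occasion.year - start.year) * 12 + occasion.month - start.month <= horizon_months:
                for slot in range(1, OBSERVERS_PER_ESCALATED_OCCASION + 1):
                    plan.append({"chimp_id": p.chimp_id, "date": occasion,
                                 "observer_slot": slot, "reason": "significant_hair_loss"})
                occasion = _add_months(occasion, ESCALATED_INTERVAL_MONTHS)
        else:
            due = _add_months(start, ROUTINE_INTERVAL_MONTHS)
            if (due.year - start.year) * 12 + due.month - start.month <= horizon_months:
                plan.append({"chimp_id": p.chimp_id, "date": due, "observer_slot": 1,
                             "reason": "routine_colony_survey"})
    return plan


def hairloss_trajectory(
    results: Sequence[HairLossResult], chimp_id: str
) -> tuple[list[HairLossResult], list[float]]:
    """Chronological series of one chimp's totals with per-interval deltas."""
    series = sorted((r for r in results if r.chimp_id == chimp_id), key=lambda r: r.date)
    if not series:
        raise ValueError(f"no results for {chimp_id!r}")
    deltas = [b.total_pct - a.total_pct for a, b in zip(series, series[1:])]
    return series, deltas
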