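"""Integrated Welfare Report: one document tying all metrics together.

The report is a pure function of the validated record stores, the
config, the subject, and the period.  Every section is always present;
a section without records in the period is explicitly marked so absence
of data is never mistaken for absence of concern.  Wound concern flags
are cross-referenced into the TIA section.  Serializes to JSON and to
human-readable Markdown.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from typing import Sequence

from . import budgets, hairloss, network, prt, wellness, wounds
from .core import ChimpProfile

__all__ = ["build_report", "report_to_markdown", "report_to_json"]

logger = logging.getLogger("chimpwelfare.report")

NO_DATA = "no data in period"


def _in_period(d: dt.date, period: tuple[dt.date, dt.date]) -> bool:
    return period[0] <= d <= period[1]


def build_report(
    subject: str,
    period: tuple[dt.date, dt.date],
    roster: Sequence[ChimpProfile],
    scans=(),
    wound_log=(),
    wellness_responses=(),
    hairloss_surveys=(),
    night_observations=(),
    prt_sessions=(),
    shift_records=(),
    behavior_reports=(),
    zone_map: hairloss.ZoneMap | None = None,
    wellness_weights=None,
) -> dict:
    """Assemble the Integrated Welfare Report for one chimp."""
    profile = next((p for p in roster if p.chimp_id == subject), None)
    if profile is None:
        raise KeyError(f"unknown subject {subject!r}")
    group = [p.chimp_id for p in roster if p.group_id == profile.group_id]
    report: dict = {
        "subject": subject,
        "group_id": profile.group_id,
        "period": [period[0].isoformat(), period[1].isoformat()],
        "sections": {},
    }

    # wellness
    responses = [r for r in wellness_responses
                 if r.chimp_id == subject and _in_period(r.date, period)]
    if responses:
        by_date: dict[dt.date, list] = {}
        for r in responses:
            by_date.setdefault(r.date, []).append(r)
        scores = [wellness.score_survey(rs, wellness_weights) for rs in by_date.values()]
        report["sections"]["wellness"] = [
            {"date": s.date.isoformat(), "total": round(s.total, 4), "band": s.band}
            for s in sorted(scores, key=lambda s: s.date)
        ]
    else:
        report["sections"]["wellness"] = NO_DATA

    # wounds
    in_period_log = [e for e in wound_log if _in_period(e.date, period)]
    subject_log = [e for e in in_period_log if e.chimp_id == subject]
    flags = [f for f in wounds.concern_flags(in_period_log) if f.chimp_id == subject]
    for f in flags:
        logger.info("wound flag fired: chimp=%s criterion=%s count=%d window=%s..%s",
                    f.chimp_id, f.criterion, f.count, f.window_start, f.window_end)
    if subject_log:
        report["sections"]["wounds"] = {
            "severity_distribution": {
                str(g): round(p, 4)
                for g, p in wounds.severity_distribution(subject_log).items()
            },
            "concern_flags": [
                {"criterion": f.criterion, "count": f.count,
                 "window_start": f.window_start.isoformat(),
                 "window_end": f.window_end.isoformat()}
                for f in flags
            ],
        }
    else:
        report["sections"]["wounds"] = NO_DATA

    # hair loss
    surveys = [s for s in hairloss_surveys
               if s.chimp_id == subject and _in_period(s.date, period)]
    if surveys:
        results = [hairloss.total_hair_loss(s, zone_map) for s in surveys]
        series, deltas = hairloss.hairloss_trajectory(results, subject)
        report["sections"]["hair_loss"] = {
            "results": [{"date": r.date.isoformat(), "total_pct": round(r.total_pct, 2),
                         "significant": r.significant} for r in series],
            "deltas_pct": [round(d, 2) for d in deltas],
        }
    else:
        report["sections"]["hair_loss"] = NO_DATA

    # activity budget + TIA triggers
    try:
        budget = budgets.budget_from_scans(scans, subject=subject, period=period)
    except ValueError:
        budget = None
    triggers = budgets.evaluate_tia_triggers(
        subject,
        reports=[r for r in behavior_reports if _in_period(r.date, period)],
        budget=budget,
        wound_flags=flags,
        as_of=period[1],
    )
    for t in triggers:
        logger.info("TIA trigger fired: chimp=%s cause=%s date=%s",
                    t.chimp_id, t.cause, t.date)
    report["sections"]["activity_budget"] = (
        {"pct": {c: round(v, 2) for c, v in budget.pct.items()},
         "n_samples": budget.n_samples}
        if budget is not None else NO_DATA
    )
    report["sections"]["tia_triggers"] = (
        [{"cause": t.cause, "date": t.date.isoformat()} for t in triggers]
        if triggers else (NO_DATA if budget is None and not flags else [])
    )

    # social
    nights = [o for o in night_observations if _in_period(o.date, period)]
    if any(o.chimp_id == subject for o in nights):
        matrix = network.pair_matrix(nights, group, stratum="all")
        report["sections"]["social"] = {
            "top_partners": network.top_partners(matrix, subject),
            "no_neighbor_nights": network.no_neighbor_counts(nights, group)[subject],
            "location": network.location_tally(nights, group)[subject],
        }
    else:
        report["sections"]["social"] = NO_DATA

    # PRT + shifting
    sessions = [s for s in prt_sessions
                if s.chimp_id == subject and _in_period(s.date, period)]
    if sessions or any(
        subject in r.complied and _in_period(r.date, period) for r in shift_records
    ):
        compliance = prt.shifting_compliance(
            [r for r in shift_records if _in_period(r.date, period)], subject
        )
        report["sections"]["prt"] = {
            "n_sessions": len(sessions),
            "shifting_compliance_pct": (
                round(compliance, 2) if compliance is not None else "undefined"
            ),
        }
    else:
        report["sections"]["prt"] = NO_DATA

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1)


def report_to_markdown(report: dict) -> str:
    lines = [
        f"# Integrated Welfare Report: {report['subject']}",
        f"Group {report['group_id']}, period {report['period'][0]} to {report['period'][1]}",
        "",
    ]
    titles = {
        "wellness": "Wellness",
        "wounds": "Wound surveillance",
        "hair_loss": "Hair loss",
        "activity_budget": "Activity budget",
        "tia_triggers": "TIA triggers",
        "social": "Nearest night neighbors",
        "prt": "Training and shifting",
    }
    for key, title in titles.items():
        lines.append(f"## {title}")
        section = report["sections"][key]
        if section == NO_DATA:
            lines.append(f"_{NO_DATA}_")
        elif isinstance(section, list) and not section:
            lines.append("_none_")
        else:
            lines.append("```json")
            lines.append(json.dumps(section, indent=1))
            lines.append("```")
        lines.append("")
    return "\n".join(lines)
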