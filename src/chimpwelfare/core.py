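"""Shared domain types, record IO, and roster name validation.

All record collections downstream modules consume are plain lists of the
dataclasses defined here.  Files are exchanged as UTF-8 CSV (header row
required) or JSON arrays whose keys mirror the CSV column names 1:1.
Dates are ISO-8601 and timezone-naive (facility local time).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import edlib
import yaml

from .defaults import (
    BEHAVIOR_CATEGORIES,
    DEFAULT_ALL_OCCURRENCE,
    DEFAULT_INSTANTANEOUS,
    WELLNESS_PARAMETERS,
)

__all__ = [
    "ChimpProfile",
    "Ethogram",
    "ObservationRecord",
    "WoundEvent",
    "WellnessResponse",
    "HairLossSurvey",
    "NightObservation",
    "PRTSession",
    "ShiftRecord",
    "BehaviorReport",
    "LoadResult",
    "SchemaError",
    "load_records",
    "write_records",
    "load_roster",
    "default_ethogram",
    "load_ethogram",
    "validate_names",
    "NameIssue",
]

PROXIMITY_CLASSES = ("contact", "arms_reach", "within_3m", "outside_3m", "no_neighbor")


class SchemaError(ValueError):
    """A file or record does not conform to its declared schema."""


@dataclass(frozen=True)
class ChimpProfile:
    chimp_id: str
    name: str
    sex: str  # "M" or "F"
    birth_date: dt.date
    group_id: str

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise SchemaError(f"sex must be M or F, got {self.sex!r}")


@dataclass(frozen=True)
class Ethogram:
    """Behavior catalogue: codes mapped to categories, split by sampling role."""

    instantaneous: dict[str, str]
    all_occurrence: dict[str, str]

    def __post_init__(self) -> None:
        overlap = set(self.instantaneous) & set(self.all_occurrence)
        if overlap:
            raise SchemaError(f"codes appear in both lists: {sorted(overlap)}")
        for code, cat in {**self.instantaneous, **self.all_occurrence}.items():
            if cat not in BEHAVIOR_CATEGORIES:
                raise SchemaError(f"code {code!r} maps to unknown category {cat!r}")

    @property
    def categories(self) -> tuple[str, ...]:
        return BEHAVIOR_CATEGORIES

    def category_of(self, code: str) -> str:
        if code in self.instantaneous:
            return self.instantaneous[code]
        if code in self.all_occurrence:
            return self.all_occurrence[code]
        raise KeyError(f"unknown behavior code {code!r}")

    def __contains__(self, code: str) -> bool:
        return code in self.instantaneous or code in self.all_occurrence


def default_ethogram() -> Ethogram:
    return Ethogram(dict(DEFAULT_INSTANTANEOUS), dict(DEFAULT_ALL_OCCURRENCE))


def load_ethogram(path: str | Path) -> Ethogram:
    """Load an ethogram from a YAML/JSON mapping with keys
    ``instantaneous`` and ``all_occurrence`` (code -> category)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return Ethogram(dict(data["instantaneous"]), dict(data["all_occurrence"]))


@dataclass(frozen=True)
class ObservationRecord:
    timestamp: dt.datetime
    observer: str
    focal_id: str
    behavior_code: str
    sampling: str  # instantaneous | all_occurrence | continuous
    duration_s: float | None = None
    neighbors_within_1m: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sampling not in ("instantaneous", "all_occurrence", "continuous"):
            raise SchemaError(f"bad sampling kind {self.sampling!r}")
        if (self.duration_s is not None) != (self.sampling == "continuous"):
            raise SchemaError("duration_s present iff sampling is continuous")
        if self.duration_s is not None and self.duration_s < 0:
            raise SchemaError("duration_s must be non-negative")


@dataclass(frozen=True)
class WoundEvent:
    wound_id: str
    chimp_id: str
    date: dt.date
    grade: int
    event_kind: str  # initial | escalation

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4, 5):
            raise SchemaError(f"wound grade must be 1-5, got {self.grade}")
        if self.event_kind not in ("initial", "escalation"):
            raise SchemaError(f"bad event_kind {self.event_kind!r}")


@dataclass(frozen=True)
class WellnessResponse:
    chimp_id: str
    observer: str
    department: str  # husbandry | behavior | veterinary
    date: dt.date
    parameters: dict[str, int]

    def __post_init__(self) -> None:
        if self.department not in ("husbandry", "behavior", "veterinary"):
            raise SchemaError(f"bad department {self.department!r}")
        missing = set(WELLNESS_PARAMETERS) - set(self.parameters)
        if missing:
            raise SchemaError(f"response missing parameters: {sorted(missing)}")
        for p, v in self.parameters.items():
            if v not in (0, 1, 2, 3):
                raise SchemaError(f"raw score for {p} must be in 0..3, got {v}")


@dataclass(frozen=True)
class HairLossSurvey:
    chimp_id: str
    date: dt.date
    observer: str
    zone_scores: dict[str, int]  # zone -> percent lost, on {0,25,50,75,100}


@dataclass(frozen=True)
class NightObservation:
    chimp_id: str
    date: dt.date
    location: str  # indoor | outdoor
    proximity: str
    neighbor_id: str | None = None

    def __post_init__(self) -> None:
        if self.location not in ("indoor", "outdoor"):
            raise SchemaError(f"bad location {self.location!r}")
        if self.proximity not in PROXIMITY_CLASSES:
            raise SchemaError(f"bad proximity {self.proximity!r}")
        if (self.neighbor_id is None) != (self.proximity == "no_neighbor"):
            raise SchemaError("neighbor_id absent exactly when proximity=no_neighbor")
        if self.neighbor_id == self.chimp_id:
            raise SchemaError("a chimp cannot be its own nearest neighbor")


@dataclass(frozen=True)
class PRTSession:
    date: dt.date
    time_of_day: str
    trainer: str
    chimp_id: str
    cue_responses: tuple[tuple[str, int], ...] = ()
    reinforcers: tuple[str, ...] = ()
    notes: str = ""
    co_trainers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for cue, score in self.cue_responses:
            if score not in (1, 2, 3):
                raise SchemaError(f"cue {cue!r}: response score must be 1-3, got {score}")


@dataclass(frozen=True)
class ShiftRecord:
    date: dt.date
    group_id: str
    shifter: str
    goal: str
    weather_excluded: bool
    alternate_goal: bool
    complied: dict[str, bool] = field(default_factory=dict)
    notes: str = ""


@dataclass(frozen=True)
class BehaviorReport:
    """An externally filed abnormal-behavior or notable-change report."""

    chimp_id: str
    date: dt.date
    description: str
    priority: str = "low"  # high | medium | low
    notable_change: bool = False

    def __post_init__(self) -> None:
        if self.priority not in ("high", "medium", "low"):
            raise SchemaError(f"bad priority {self.priority!r}")


# ---------------------------------------------------------------------------
# Record IO
# ---------------------------------------------------------------------------

def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s.strip())


def _parse_datetime(s: str) -> dt.datetime:
    return dt.datetime.fromisoformat(s.strip())


def _opt(s: str) -> str | None:
    return s if s not in ("", None) else None


def _split_list(s: str) -> tuple[str, ...]:
    return tuple(x for x in (s or "").split(";") if x)


def _join_list(xs: Iterable[str]) -> str:
    return ";".join(xs)


def _row_to_observation(row: dict[str, str]) -> ObservationRecord:
    dur = _opt(row.get("duration_s", ""))
    return ObservationRecord(
        timestamp=_parse_datetime(row["timestamp"]),
        observer=row["observer"],
        focal_id=row["focal_id"],
        behavior_code=row["behavior_code"],
        sampling=row["sampling"],
        duration_s=float(dur) if dur is not None else None,
        neighbors_within_1m=_split_list(row.get("neighbors_within_1m", "")),
    )


def _observation_to_row(r: ObservationRecord) -> dict[str, str]:
    return {
        "timestamp": r.timestamp.isoformat(),
        "observer": r.observer,
        "focal_id": r.focal_id,
        "behavior_code": r.behavior_code,
        "sampling": r.sampling,
        "duration_s": "" if r.duration_s is None else repr(r.duration_s),
        "neighbors_within_1m": _join_list(r.neighbors_within_1m),
    }


def _row_to_wound(row: dict[str, str]) -> WoundEvent:
    return WoundEvent(
        wound_id=row["wound_id"],
        chimp_id=row["chimp_id"],
        date=_parse_date(row["date"]),
        grade=int(row["grade"]),
        event_kind=row["event_kind"],
    )


def _wound_to_row(r: WoundEvent) -> dict[str, str]:
    return {
        "wound_id": r.wound_id,
        "chimp_id": r.chimp_id,
        "date": r.date.isoformat(),
        "grade": str(r.grade),
        "event_kind": r.event_kind,
    }


def _row_to_wellness(row: dict[str, str]) -> WellnessResponse:
    params = {p: int(row[p]) for p in WELLNESS_PARAMETERS if p in row}
    return WellnessResponse(
        chimp_id=row["chimp_id"],
        observer=row["observer"],
        department=row["department"],
        date=_parse_date(row["date"]),
        parameters=params,
    )


def _wellness_to_row(r: WellnessResponse) -> dict[str, str]:
    row = {
        "chimp_id": r.chimp_id,
        "observer": r.observer,
        "department": r.department,
        "date": r.date.isoformat(),
    }
    row.update({p: str(v) for p, v in r.parameters.items()})
    return row


def _row_to_hairloss(row: dict[str, str]) -> HairLossSurvey:
    fixed = {"chimp_id", "date", "observer"}
    zones = {k: int(row[k]) for k in row if k not in fixed and row[k] != ""}
    return HairLossSurvey(
        chimp_id=row["chimp_id"],
        date=_parse_date(row["date"]),
        observer=row["observer"],
        zone_scores=zones,
    )


def _hairloss_to_row(r: HairLossSurvey) -> dict[str, str]:
    row = {"chimp_id": r.chimp_id, "date": r.date.isoformat(), "observer": r.observer}
    row.update({z: str(v) for z, v in r.zone_scores.items()})
    return row


def _row_to_night(row: dict[str, str]) -> NightObservation:
    return NightObservation(
        chimp_id=row["chimp_id"],
        date=_parse_date(row["date"]),
        location=row["location"],
        proximity=row["proximity"],
        neighbor_id=_opt(row.get("neighbor_id", "")),
    )


def _night_to_row(r: NightObservation) -> dict[str, str]:
    return {
        "chimp_id": r.chimp_id,
        "date": r.date.isoformat(),
        "location": r.location,
        "proximity": r.proximity,
        "neighbor_id": r.neighbor_id or "",
    }


def _row_to_prt(row: dict[str, str]) -> PRTSession:
    cues = tuple(
        (c.split(":")[0], int(c.split(":")[1]))
        for c in _split_list(row.get("cue_responses", ""))
    )
    return PRTSession(
        date=_parse_date(row["date"]),
        time_of_day=row["time_of_day"],
        trainer=row["trainer"],
        chimp_id=row["chimp_id"],
        cue_responses=cues,
        reinforcers=_split_list(row.get("reinforcers", "")),
        notes=row.get("notes", ""),
        co_trainers=_split_list(row.get("co_trainers", "")),
    )


def _prt_to_row(r: PRTSession) -> dict[str, str]:
    return {
        "date": r.date.isoformat(),
        "time_of_day": r.time_of_day,
        "trainer": r.trainer,
        "chimp_id": r.chimp_id,
        "cue_responses": _join_list(f"{c}:{s}" for c, s in r.cue_responses),
        "reinforcers": _join_list(r.reinforcers),
        "notes": r.notes,
        "co_trainers": _join_list(r.co_trainers),
    }


def _row_to_shift(row: dict[str, str]) -> ShiftRecord:
    complied = {}
    for item in _split_list(row.get("complied", "")):
        cid, flag = item.split(":")
        complied[cid] = flag == "1"
    return ShiftRecord(
        date=_parse_date(row["date"]),
        group_id=row["group_id"],
        shifter=row["shifter"],
        goal=row.get("goal", ""),
        weather_excluded=row.get("weather_excluded", "0") == "1",
        alternate_goal=row.get("alternate_goal", "0") == "1",
        complied=complied,
        notes=row.get("notes", ""),
    )


def _shift_to_row(r: ShiftRecord) -> dict[str, str]:
    return {
        "date": r.date.isoformat(),
        "group_id": r.group_id,
        "shifter": r.shifter,
        "goal": r.goal,
        "weather_excluded": "1" if r.weather_excluded else "0",
        "alternate_goal": "1" if r.alternate_goal else "0",
        "complied": _join_list(f"{c}:{int(v)}" for c, v in r.complied.items()),
        "notes": r.notes,
    }


def _row_to_report(row: dict[str, str]) -> BehaviorReport:
    return BehaviorReport(
        chimp_id=row["chimp_id"],
        date=_parse_date(row["date"]),
        description=row.get("description", ""),
        priority=row.get("priority", "low"),
        notable_change=row.get("notable_change", "0") == "1",
    )


def _report_to_row(r: BehaviorReport) -> dict[str, str]:
    return {
        "chimp_id": r.chimp_id,
        "date": r.date.isoformat(),
        "description": r.description,
        "priority": r.priority,
        "notable_change": "1" if r.notable_change else "0",
    }


def _row_to_profile(row: dict[str, str]) -> ChimpProfile:
    return ChimpProfile(
        chimp_id=row["chimp_id"],
        name=row["name"],
        sex=row["sex"],
        birth_date=_parse_date(row["birth_date"]),
        group_id=row["group_id"],
    )


def _profile_to_row(r: ChimpProfile) -> dict[str, str]:
    return {
        "chimp_id": r.chimp_id,
        "name": r.name,
        "sex": r.sex,
        "birth_date": r.birth_date.isoformat(),
        "group_id": r.group_id,
    }


_SCHEMAS: dict[str, tuple[Callable, Callable, tuple[str, ...]]] = {
    # kind: (row->record, record->row, required columns)
    "observation": (_row_to_observation, _observation_to_row,
                    ("timestamp", "observer", "focal_id", "behavior_code", "sampling")),
    "wound": (_row_to_wound, _wound_to_row,
              ("wound_id", "chimp_id", "date", "grade", "event_kind")),
    "wellness": (_row_to_wellness, _wellness_to_row,
                 ("chimp_id", "observer", "department", "date") + tuple(WELLNESS_PARAMETERS)),
    "hairloss": (_row_to_hairloss, _hairloss_to_row,
                 ("chimp_id", "date", "observer")),
    "night": (_row_to_night, _night_to_row,
              ("chimp_id", "date", "location", "proximity")),
    "prt": (_row_to_prt, _prt_to_row,
            ("date", "time_of_day", "trainer", "chimp_id")),
    "shift": (_row_to_shift, _shift_to_row,
              ("date", "group_id", "shifter")),
    "report": (_row_to_report, _report_to_row,
               ("chimp_id", "date")),
    "profile": (_row_to_profile, _profile_to_row,
                ("chimp_id", "name", "sex", "birth_date", "group_id")),
}

RECORD_KINDS = tuple(_SCHEMAS)


@dataclass
class LoadResult:
    """Records parsed from a file plus any rejected rows (line number, reason)."""

    records: list[Any]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def load_records(path: str | Path, kind: str, malformed: str = "raise") -> LoadResult:
    """Read a CSV or JSON record file into validated records.

    Parameters
    ----------
    path
        File to read; ``.json`` suffix selects the JSON reader, anything
        else is treated as CSV with a mandatory header row.
    kind
        One of :data:`RECORD_KINDS`.
    malformed
        ``"raise"`` (default) aborts on the first bad row with its line
        number; ``"skip"`` collects bad rows in ``LoadResult.rejected``.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown record kind {kind!r}; valid: {RECORD_KINDS}")
    if malformed not in ("raise", "skip"):
        raise ValueError("malformed policy must be 'raise' or 'skip'")
    parse, _, required = _SCHEMAS[kind]
    path = Path(path)

    rows: list[tuple[int, dict[str, str]]]
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        rows = [(i + 1, {k: str(v) if v is not None else "" for k, v in row.items()})
                for i, row in enumerate(data)]
        header = set(rows[0][1]) if rows else set(required)
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, header row required")
            header = set(reader.fieldnames)
            rows = [(reader.line_num, row) for row in reader]

    missing = set(required) - header
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")

    result = LoadResult(records=[])
    for lineno, row in rows:
        try:
            result.records.append(parse(row))
        except (SchemaError, ValueError, KeyError) as exc:
            if malformed == "raise":
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            result.rejected.append((lineno, str(exc)))
    return result


def write_records(path: str | Path, records: Sequence[Any], kind: str) -> None:
    """Write records to CSV or JSON (chosen by suffix); inverse of load_records."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown record kind {kind!r}; valid: {RECORD_KINDS}")
    _, unparse, required = _SCHEMAS[kind]
    path = Path(path)
    rows = [unparse(r) for r in records]
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
        return
    fieldnames: list[str] = list(required)
    for row in rows:
        for k in row:
            if k not in fieldnames:
                fieldnames.append(k)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def load_roster(path: str | Path) -> list[ChimpProfile]:
    roster = load_records(path, "profile").records
    ids = [p.chimp_id for p in roster]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate chimp_id(s) in roster: {dupes}")
    return roster


# ---------------------------------------------------------------------------
# Name validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NameIssue:
    record_index: int
    field: str
    value: str
    suggestion: str | None
    distance: int | None


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _name_fields(record: Any) -> list[tuple[str, str]]:
    """All (field, chimp-key) pairs a record carries."""
    pairs: list[tuple[str, str]] = []
    for f in dataclasses.fields(record):
        if f.name in ("chimp_id", "focal_id") :
            pairs.append((f.name, getattr(record, f.name)))
        elif f.name in ("neighbor_id",):
            v = getattr(record, f.name)
            if v is not None:
                pairs.append((f.name, v))
        elif f.name == "neighbors_within_1m":
            for v in getattr(record, f.name):
                pairs.append((f.name, v))
        elif f.name == "complied":
            for v in getattr(record, f.name):
                pairs.append((f.name, v))
    return pairs


def validate_names(
    records: Iterable[Any],
    roster: Sequence[ChimpProfile] | Sequence[str],
    case_insensitive: bool = True,
) -> list[NameIssue]:
    """Flag records naming chimps absent from the roster.

    Misspelled observer-entered names silently corrupt downstream counts,
    so every unknown key is reported together with the nearest roster
    name by Levenshtein edit distance (ties broken alphabetically).
    Matching is case-insensitive by default; unknown names are report
    content, never exceptions.
    """
    names = [p.chimp_id if isinstance(p, ChimpProfile) else str(p) for p in roster]
    if not names:
        raise ValueError("roster must be non-empty")
    lookup = {n.casefold() if case_insensitive else n for n in names}

    issues: list[NameIssue] = []
    for idx, record in enumerate(records):
        for fieldname, value in _name_fields(record):
            key = value.casefold() if case_insensitive else value
            if key in lookup:
                continue
            ranked = sorted(names, key=lambda n: (_levenshtein(value, n), n))
            best = ranked[0]
            issues.append(NameIssue(idx, fieldname, value, best, _levenshtein(value, best)))
    return issues
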