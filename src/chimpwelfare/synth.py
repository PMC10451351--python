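"""Seeded synthetic colony simulator with a ground-truth manifest.

Real sanctuary records are private, so every metric module is exercised
against simulated streams whose generating parameters are known.  The
simulator emulates:

* instantaneous scan points drawn per chimp from a behavior-category
  mixture (default: an inactive-dominant colony budget typical of
  sanctuary chimpanzees);
* continuous focal sessions segmented from the same mixture;
* wound events as Poisson arrivals per chimp-day with an ordinal
  severity distribution and occasional escalations;
* multi-assessor wellness responses with scores concentrated at zero;
* bounded hair-loss trajectories on the five-point zone scale;
* nightly nearest-neighbor choices proportional to a symmetric pairwise
  preference matrix (with an optional planted strongest pair), plus
  no-neighbor and indoor/outdoor probabilities;
* Bernoulli shifting compliance and PRT cue-response logs.

Each record stream draws from its own child generator spawned from the
master seed, so adding a stream never perturbs the others.  The returned
manifest records every generating parameter for recovery checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .core import (
    BehaviorReport,
    ChimpProfile,
    Ethogram,
    HairLossSurvey,
    NightObservation,
    ObservationRecord,
    PRTSession,
    ShiftRecord,
    WellnessResponse,
    WoundEvent,
    default_ethogram,
    write_records,
)
from .defaults import BEHAVIOR_CATEGORIES, DEFAULT_ZONE_WEIGHTS, WELLNESS_PARAMETERS
from . import budgets, network, prt, wounds as wounds_mod

__all__ = ["ColonyConfig", "Bundle", "simulate", "recovery_report"]

#: default colony-level behavior mixture (inactive-dominant), over the
#: nine budget categories; illustrative of a sanctuary colony, not fitted.
DEFAULT_MIXTURE = {
    "inactive": 0.5117,
    "food_drink": 0.1624,
    "self_directed": 0.1057,
    "locomotion": 0.0907,
    "affiliative": 0.0668,
    "abnormal": 0.0200,
    "aggressive": 0.0150,
    "sexual": 0.0100,
    "other": 0.0177,
}

#: default wound severity distribution over grades 1-5 (superficial-dominant)
DEFAULT_SEVERITY = (0.5162, 0.3006, 0.1361, 0.0350, 0.0121)

#: raw wellness score distribution per parameter per assessor (mostly 0)
DEFAULT_WELLNESS_SCORE_DIST = (0.90, 0.07, 0.02, 0.01)

PROXIMITY_DIST = {"contact": 0.30, "arms_reach": 0.30, "within_3m": 0.25, "outside_3m": 0.15}


@dataclass
class ColonyConfig:
    n_chimps: int = 12
    group_sizes: tuple[int, ...] = (6, 6)
    start_date: dt.date = dt.date(2022, 1, 1)
    n_days: int = 180
    # scans / focals
    behavior_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    per_chimp_mixtures: dict[str, dict[str, float]] | None = None
    n_scans_per_chimp: int = 200
    n_focal_sessions_per_chimp: int = 10
    focal_session_s: int = 900
    focal_segment_s: int = 30
    all_occurrence_rate_per_hour: float = 0.5
    # wounds
    wound_rate_per_chimp_day: float = 0.01
    severity_distribution: tuple[float, ...] = DEFAULT_SEVERITY
    escalation_prob: float = 0.05
    # wellness
    n_assessors: int = 3
    wellness_score_dist: tuple[float, ...] = DEFAULT_WELLNESS_SCORE_DIST
    # hair loss
    hairloss_mean_pct: float = 8.0
    hairloss_sd_pct: float = 12.0
    hairloss_drift_sd_pct: float = 5.0
    n_hairloss_surveys: int = 2
    # night observations
    n_nights: int = 100
    no_neighbor_prob: float = 0.10
    indoor_prob: float = 0.90
    preference_weight: float = 1.0
    planted_pair_weight: float = 6.0
    # PRT / shifting
    prt_sessions_per_chimp: int = 8
    shift_days: int = 60
    shift_compliance_prob: float | dict[str, float] = 0.8
    weather_excluded_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_chimps:
            raise ValueError("group sizes must sum to n_chimps")
        self._check_mixture(self.behavior_mixture)
        if self.per_chimp_mixtures:
            for m in self.per_chimp_mixtures.values():
                self._check_mixture(m)
        if abs(sum(self.severity_distribution) - 1.0) > 1e-9:
            raise ValueError("severity distribution must sum to 1")
        if self.wound_rate_per_chimp_day < 0:
            raise ValueError("wound rate must be nonnegative")

    @staticmethod
    def _check_mixture(m: dict[str, float]) -> None:
        if set(m) - set(BEHAVIOR_CATEGORIES):
            raise ValueError(f"unknown categories: {sorted(set(m) - set(BEHAVIOR_CATEGORIES))}")
        if any(v < 0 for v in m.values()) or abs(sum(m.values()) - 1.0) > 1e-9:
            raise ValueError("behavior mixture must be a probability vector")


@dataclass
class Bundle:
    roster: list[ChimpProfile]
    scans: list[ObservationRecord]
    focals: list[ObservationRecord]
    wounds: list[WoundEvent]
    wellness_responses: list[WellnessResponse]
    hairloss_surveys: list[HairLossSurvey]
    night_observations: list[NightObservation]
    prt_sessions: list[PRTSession]
    shift_records: list[ShiftRecord]
    reports: list[BehaviorReport]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        """Write the full CSV bundle plus the JSON ground-truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records(outdir / "roster.csv", self.roster, "profile")
        write_records(outdir / "scans.csv", self.scans, "observation")
        write_records(outdir / "focals.csv", self.focals, "observation")
        write_records(outdir / "wounds.csv", self.wounds, "wound")
        write_records(outdir / "wellness.csv", self.wellness_responses, "wellness")
        write_records(outdir / "hairloss.csv", self.hairloss_surveys, "hairloss")
        write_records(outdir / "nights.csv", self.night_observations, "night")
        write_records(outdir / "prt.csv", self.prt_sessions, "prt")
        write_records(outdir / "shifts.csv", self.shift_records, "shift")
        write_records(outdir / "reports.csv", self.reports, "report")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def _choice(rng: np.random.Generator, items: Sequence, p=None):
    return items[int(rng.choice(len(items), p=p))]


def simulate(config: ColonyConfig, ethogram: Ethogram | None = None) -> Bundle:
    """Generate a full record bundle, deterministic given ``config.seed``."""
    eth = ethogram or default_ethogram()
    codes_by_cat: dict[str, list[str]] = {c: [] for c in BEHAVIOR_CATEGORIES}
    for code, cat in eth.instantaneous.items():
        codes_by_cat[cat].append(code)
    ao_codes = list(eth.all_occurrence)

    streams = np.random.SeedSequence(config.seed).spawn(9)
    (rng_roster, rng_scan, rng_focal, rng_wound, rng_well,
     rng_hair, rng_night, rng_prt, rng_shift) = (np.random.default_rng(s) for s in streams)

    # --- roster ------------------------------------------------------------
    roster: list[ChimpProfile] = []
    gid = 0
    idx = 0
    for size in config.group_sizes:
        gid += 1
        for _ in range(size):
            idx += 1
            cid = f"C{idx:03d}"
            age_years = int(rng_roster.integers(4, 60))
            birth = config.start_date - dt.timedelta(days=365 * age_years)
            roster.append(ChimpProfile(
                chimp_id=cid, name=cid,
                sex="M" if rng_roster.random() < 0.45 else "F",
                birth_date=birth, group_id=f"G{gid}",
            ))
    ids = [p.chimp_id for p in roster]
    groups: dict[str, list[str]] = {}
    for p in roster:
        groups.setdefault(p.group_id, []).append(p.chimp_id)

    mixtures = {
        cid: (config.per_chimp_mixtures or {}).get(cid, config.behavior_mixture)
        for cid in ids
    }

    # --- instantaneous scans + all-occurrence events -----------------------
    cats = list(BEHAVIOR_CATEGORIES)
    scans: list[ObservationRecord] = []
    for cid in ids:
        p = np.array([mixtures[cid].get(c, 0.0) for c in cats])
        days = rng_scan.integers(0, config.n_days, size=config.n_scans_per_chimp)
        secs = rng_scan.integers(0, 8 * 3600, size=config.n_scans_per_chimp)
        cat_idx = rng_scan.choice(len(cats), size=config.n_scans_per_chimp, p=p)
        for k in range(config.n_scans_per_chimp):
            cat = cats[int(cat_idx[k])]
            code = _choice(rng_scan, codes_by_cat[cat] or ["rest"])
            ts = dt.datetime.combine(
                config.start_date + dt.timedelta(days=int(days[k])),
                dt.time(7, 30),
            ) + dt.timedelta(seconds=int(secs[k]))
            scans.append(ObservationRecord(
                timestamp=ts, observer="sim", focal_id=cid,
                behavior_code=code, sampling="instantaneous",
            ))
        # rare all-occurrence events over the scan effort
        hours = config.n_scans_per_chimp / 60.0  # nominal one scan per minute
        n_events = rng_scan.poisson(config.all_occurrence_rate_per_hour * hours)
        for _ in range(n_events):
            ts = dt.datetime.combine(
                config.start_date + dt.timedelta(days=int(rng_scan.integers(0, config.n_days))),
                dt.time(9, 0),
            )
            scans.append(ObservationRecord(
                timestamp=ts, observer="sim", focal_id=cid,
                behavior_code=_choice(rng_scan, ao_codes), sampling="all_occurrence",
            ))

    # --- focal sessions ----------------------------------------------------
    focals: list[ObservationRecord] = []
    n_seg = config.focal_session_s // config.focal_segment_s
    for cid in ids:
        p = np.array([mixtures[cid].get(c, 0.0) for c in cats])
        for s in range(config.n_focal_sessions_per_chimp):
            day = int(rng_focal.integers(0, config.n_days))
            t0 = dt.datetime.combine(
                config.start_date + dt.timedelta(days=day), dt.time(8, 0)
            ) + dt.timedelta(minutes=20 * s)
            seg_cats = rng_focal.choice(len(cats), size=n_seg, p=p)
            for k in range(n_seg):
                cat = cats[int(seg_cats[k])]
                code = _choice(rng_focal, codes_by_cat[cat] or ["rest"])
                focals.append(ObservationRecord(
                    timestamp=t0 + dt.timedelta(seconds=k * config.focal_segment_s),
                    observer="sim", focal_id=cid, behavior_code=code,
                    sampling="continuous", duration_s=float(config.focal_segment_s),
                ))

    # --- wounds ------------------------------------------------------------
    wound_events: list[WoundEvent] = []
    sev = np.asarray(config.severity_distribution)
    wid = 0
    for cid in ids:
        n_wounds = rng_wound.poisson(config.wound_rate_per_chimp_day * config.n_days)
        for _ in range(n_wounds):
            wid += 1
            day = int(rng_wound.integers(0, config.n_days))
            grade = int(rng_wound.choice(5, p=sev)) + 1
            date = config.start_date + dt.timedelta(days=day)
            wound_events.append(WoundEvent(
                wound_id=f"W{wid:05d}", chimp_id=cid, date=date,
                grade=grade, event_kind="initial",
            ))
            if grade < 5 and rng_wound.random() < config.escalation_prob:
                wound_events.append(WoundEvent(
                    wound_id=f"W{wid:05d}", chimp_id=cid,
                    date=date + dt.timedelta(days=int(rng_wound.integers(1, 8))),
                    grade=grade + 1, event_kind="escalation",
                ))
    wound_events.sort(key=lambda e: (e.date, e.wound_id))

    # --- wellness responses -------------------------------------------------
    wellness: list[WellnessResponse] = []
    departments = ("husbandry", "behavior", "veterinary")
    score_p = np.asarray(config.wellness_score_dist)
    for cid in ids:
        date = config.start_date + dt.timedelta(days=int(rng_well.integers(0, config.n_days)))
        for a in range(config.n_assessors):
            params = {p_: int(rng_well.choice(4, p=score_p)) for p_ in WELLNESS_PARAMETERS}
            wellness.append(WellnessResponse(
                chimp_id=cid, observer=f"assessor{a + 1}",
                department=departments[a % 3], date=date, parameters=params,
            ))

    # --- hair-loss surveys --------------------------------------------------
    hair: list[HairLossSurvey] = []
    zones = list(DEFAULT_ZONE_WEIGHTS)
    hair_truth: dict[str, list[float]] = {}
    for cid in ids:
        level = float(np.clip(rng_hair.normal(config.hairloss_mean_pct,
                                              config.hairloss_sd_pct), 0, 100))
        hair_truth[cid] = []
        for s in range(config.n_hairloss_surveys):
            hair_truth[cid].append(level)
            scores = {}
            for z in zones:
                obs = float(np.clip(level + rng_hair.normal(0, 6.0), 0, 100))
                scores[z] = min((0, 25, 50, 75, 100), key=lambda pt: (abs(pt - obs), -pt))
            hair.append(HairLossSurvey(
                chimp_id=cid,
                date=config.start_date + dt.timedelta(days=90 * s),
                observer="sim", zone_scores=scores,
            ))
            level = float(np.clip(level + rng_hair.normal(0, config.hairloss_drift_sd_pct),
                                  0, 100))

    # --- night observations --------------------------------------------------
    nights: list[NightObservation] = []
    prox_classes = list(PROXIMITY_DIST)
    prox_p = np.asarray([PROXIMITY_DIST[c] for c in prox_classes])
    pref_matrices: dict[str, list[list[float]]] = {}
    planted_pairs: dict[str, tuple[str, str]] = {}
    for group_id, members in groups.items():
        n = len(members)
        pref = np.full((n, n), config.preference_weight)
        np.fill_diagonal(pref, 0.0)
        if n >= 2 and config.planted_pair_weight > config.preference_weight:
            pref[0, 1] = pref[1, 0] = config.planted_pair_weight
            planted_pairs[group_id] = (members[0], members[1])
        pref_matrices[group_id] = pref.tolist()
        for night in range(config.n_nights):
            date = config.start_date + dt.timedelta(days=night)
            for i, cid in enumerate(members):
                location = "indoor" if rng_night.random() < config.indoor_prob else "outdoor"
                if n < 2 or rng_night.random() < config.no_neighbor_prob:
                    nights.append(NightObservation(
                        chimp_id=cid, date=date, location=location,
                        proximity="no_neighbor", neighbor_id=None,
                    ))
                    continue
                w = pref[i] / pref[i].sum()
                j = int(rng_night.choice(n, p=w))
                nights.append(NightObservation(
                    chimp_id=cid, date=date, location=location,
                    proximity=_choice(rng_night, prox_classes, p=prox_p),
                    neighbor_id=members[j],
                ))

    # --- PRT sessions ---------------------------------------------------------
    prt_sessions: list[PRTSession] = []
    cues = ("target", "present_arm", "open_mouth", "station")
    for cid in ids:
        for s in range(config.prt_sessions_per_chimp):
            day = int(rng_prt.integers(0, config.n_days))
            cue = _choice(rng_prt, cues)
            score = int(rng_prt.choice(3, p=(0.15, 0.25, 0.60))) + 1
            prt_sessions.append(PRTSession(
                date=config.start_date + dt.timedelta(days=day),
                time_of_day=f"{int(rng_prt.integers(8, 16)):02d}:00",
                trainer=f"trainer{int(rng_prt.integers(1, 5))}",
                chimp_id=cid,
                cue_responses=((cue, score),),
                reinforcers=("juice",),
            ))

    # --- shifting records ------------------------------------------------------
    comp = config.shift_compliance_prob
    comp_probs = {cid: (comp[cid] if isinstance(comp, dict) else comp) for cid in ids}
    shifts: list[ShiftRecord] = []
    for group_id, members in groups.items():
        for day in range(config.shift_days):
            date = config.start_date + dt.timedelta(days=day)
            weather = bool(rng_shift.random() < config.weather_excluded_prob)
            complied = {cid: bool(rng_shift.random() < comp_probs[cid]) for cid in members}
            shifts.append(ShiftRecord(
                date=date, group_id=group_id, shifter="shifter1",
                goal="shift outside", weather_excluded=weather,
                alternate_goal=False, complied=complied,
            ))

    manifest = {
        "seed": config.seed,
        "n_chimps": config.n_chimps,
        "groups": groups,
        "behavior_mixtures": mixtures,
        "wound_rate_per_chimp_day": config.wound_rate_per_chimp_day,
        "severity_distribution": list(config.severity_distribution),
        "preference_matrices": pref_matrices,
        "planted_pairs": {g: list(p) for g, p in planted_pairs.items()},
        "no_neighbor_prob": config.no_neighbor_prob,
        "indoor_prob": config.indoor_prob,
        "shift_compliance_probs": comp_probs,
        "hairloss_levels": hair_truth,
        "n_nights": config.n_nights,
    }
    return Bundle(
        roster=roster, scans=scans, focals=focals, wounds=wound_events,
        wellness_responses=wellness, hairloss_surveys=hair,
        night_observations=nights, prt_sessions=prt_sessions,
        shift_records=shifts, reports=[], manifest=manifest,
    )


def recovery_report(bundle: Bundle, manifest: dict | None = None) -> dict:
    """Estimate-vs-truth errors for the main recoverable quantities.

    Reports, per chimp, the maximum absolute budget error (percentage
    points); the maximum absolute severity-distribution error; per-chimp
    absolute compliance error (zero for noiseless 0/1 probabilities);
    and whether each group's planted strongest pair is recovered as the
    top sociogram edge.
    """
    m = manifest or bundle.manifest
    out: dict = {"budget_max_abs_err_pct": {}, "compliance_abs_err_pct": {},
                 "planted_pair_recovered": {}}

    for cid, mixture in m["behavior_mixtures"].items():
        try:
            b = budgets.budget_from_scans(bundle.scans, subject=cid)
        except ValueError:
            continue
        err = max(abs(b.pct[c] - 100.0 * mixture.get(c, 0.0)) for c in b.pct)
        out["budget_max_abs_err_pct"][cid] = err

    if bundle.wounds:
        est = wounds_mod.severity_distribution(bundle.wounds)
        truth = m["severity_distribution"]
        # escalations shift mass upward; compare against initial grades only
        initial = [e for e in bundle.wounds if e.event_kind == "initial"]
        from collections import Counter
        counts = Counter(e.grade for e in initial)
        n = sum(counts.values())
        out["severity_max_abs_err"] = max(
            abs(counts.get(g + 1, 0) / n - truth[g]) for g in range(5)
        )
        out["n_effective_wounds"] = len({e.wound_id for e in bundle.wounds})

    for cid, p in m["shift_compliance_probs"].items():
        est = prt.shifting_compliance(bundle.shift_records, cid)
        if est is not None:
            out["compliance_abs_err_pct"][cid] = abs(est - 100.0 * p)

    for group_id, pair in m.get("planted_pairs", {}).items():
        members = m["groups"][group_id]
        mat = network.pair_matrix(bundle.night_observations, members, stratum="all")
        edges = mat.edges()
        if edges:
            top = max(edges, key=lambda e: e[2])
            out["planted_pair_recovered"][group_id] = set(top[:2]) == set(pair)
    return out
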