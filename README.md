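# chimpwelfare

Behavioral-welfare metric toolkit for managed chimpanzee colonies —
sanctuaries, zoos, and research facilities that monitor large groups of
*Pan troglodytes* with small behavior teams.

Welfare staff collect heterogeneous streams: ethogram-based behavior
scans, wound reports, multi-assessor wellness surveys, hair-loss zone
scores, nightly nearest-neighbor records, training logs, and shifting
logs. This package turns those streams into the seven quantitative
protocols used to manage a colony:

1. **Wellness scoring** — ten parameters rated 0–3 by multiple
   assessors; `Total = Σ_p w_p · mean(raw_p)` on a 0–30 scale, banded
   into routine (< 12), elevated (12–29), and critical (> 29), with
   quarterly survey scheduling.
2. **Wound surveillance** — grade 1–5 events deduplicated per wound at
   max in-window grade; rolling 14-day concern criteria (10 of any
   grade / 4 grade-3 / 3 grade-4 / 1 grade-5), proven equivalent to
   brute-force window enumeration.
3. **Hair loss** — zone scores on {0,25,50,75,100} weighted by each
   zone's share of ideal hair surface; `total = Σ_z w_z s_z`; ≥ 25%
   escalates monitoring.
4. **Activity budgets & TIA** — instantaneous-scan and continuous-focal
   time budgets, all-occurrence rates, Targeted Individual Assessment
   triggers (abnormal share strictly > 10%, wound flags, high-priority
   reports), and pre/post-intervention deltas.
5. **SMS scheduler** — the 13-reason observation table (e.g.
   Post-Social Integration → 13 observations / 3 months) with seeded
   slot assignment over three daily time blocks.
6. **Nearest night neighbors** — per-night pair counting into
   proximity-stratified sociogram matrices, no-neighbor tallies,
   indoor/outdoor splits, seeded force-directed layouts.
7. **PRT & shifting analytics** — session IDs, engagement summaries,
   cue-response trends on the 1–3 scale, and shifting compliance
   (complied / eligible asked-days, weather days excluded).

A seeded synthetic colony simulator generates every stream from known
ground truth, and an Integrated Welfare Report cross-references all
metrics for one animal. See `docs/methods.md` for models, defaults, and
numerical choices.

## Worked example

```python
import datetime as dt
from chimpwelfare import WoundEvent, concern_flags, severity_distribution

d0 = dt.date(2022, 5, 1)
log = (
    [WoundEvent(f"p{i}", "Pamela", d0 + dt.timedelta(days=i), 1 + i % 2, "initial")
     for i in range(10)]
    + [WoundEvent("d1", "Duke", d0 + dt.timedelta(days=2), 3, "initial"),
       WoundEvent("d1", "Duke", d0 + dt.timedelta(days=7), 4, "escalation"),
       WoundEvent("k1", "Kino", d0 + dt.timedelta(days=12), 5, "initial")]
)
for f in concern_flags(log):
    print(f.chimp_id, f.criterion, f.count, f.window_start, f.window_end)
print({g: round(p, 4) for g, p in severity_distribution(log).items()})
```

prints

```
Pamela any_grade_total 10 2022-04-27 2022-05-10
Kino grade5_count 1 2022-04-30 2022-05-13
{1: 0.4167, 2: 0.4167, 4: 0.0833, 5: 0.0833}
```

Pamela's ten wounds inside one 14-day window trip the any-grade
criterion and Kino's single grade-5 wound flags immediately, while
Duke's one escalated wound stays below every threshold; the severity
distribution counts each wound once at its maximum grade (Duke's wound
appears as the grade-4 share). The `examples/` directory has one short
script per capability; each prints its numbers with a line on what they
mean. A thin CLI mirrors the library
(`welfare simulate | wellness | wounds | hairloss | budget | sms | tia | nnn | prt | report`).

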