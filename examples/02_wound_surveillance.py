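"""Rolling-window wound surveillance on a small hand-built log.

Wounds are graded 1 (superficial) to 5 (gaping / missing body part); the
log records only initial occurrences and escalations.  Concern criteria
over any 14-day window: 10 wounds of any grade, 4 grade-3, 3 grade-4, or
a single grade-5 wound.
"""

import datetime as dt

from chimpwelfare import WoundEvent, concern_flags, severity_distribution, wound_timeline

d0 = dt.date(2022, 5, 1)


def wound(wid, chimp, day, grade, kind="initial"):
    return WoundEvent(wid, chimp, d0 + dt.timedelta(days=day), grade, kind)


log = (
    # Pamela: a burst of minor wounds after an introduction — 10 within two weeks
    [wound(f"p{i}", "Pamela", i, 1 + i % 2) for i in range(10)]
    # Duke: one moderate wound that escalates to grade 4 five days later
    + [wound("d1", "Duke", 2, 3), wound("d1", "Duke", 7, 4, "escalation")]
    # Kino: a single severe grade-5 wound
    + [wound("k1", "Kino", 12, 5)]
)

for f in concern_flags(log):
    print(f"flag: {f.chimp_id:7s} {f.criterion:15s} count={f.count} "
          f"window {f.window_start} .. {f.window_end}")

# Pamela trips the 10-wounds-of-any-grade criterion, Kino the grade-5
# criterion; Duke's single escalated wound stays below every threshold.

dist = severity_distribution(log)
print("severity distribution (effective wounds, max grade):",
      {g: round(p, 3) for g, p in dist.items()})

timeline = wound_timeline(log, bin="week")
print("wounds per ISO week:", {w: dict(c) for w, c in sorted(timeline.items())})
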