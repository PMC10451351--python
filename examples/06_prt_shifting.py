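"""PRT engagement and shifting compliance for one focal chimp.

Each training session is keyed by (date, time, trainer, chimp); cue
responses use the 1-3 scale.  Shifting compliance is the percentage of
eligible asked-days a chimp moved as requested, with weather-excluded
and alternate-goal days removed from the denominator.
"""

import datetime as dt

from chimpwelfare import (
    PRTSession,
    ShiftRecord,
    engagement_summary,
    session_id,
    shifting_compliance,
)
from chimpwelfare.core import ChimpProfile

d0 = dt.date(2021, 6, 1)

roster = [ChimpProfile(n, n, "F", dt.date(1994, 1, 1), "G1")
          for n in ("Latoya", "Tessa", "Slim", "Nina")]

sessions = [
    PRTSession(d0 + dt.timedelta(days=7 * k), "09:00", "trainer1", "Latoya",
               cue_responses=(("station", 2 if k < 4 else 3),))
    for k in range(8)
]
print("first session ID:", session_id(sessions[0].date, "09:00", "trainer1", "Latoya"))

summary = engagement_summary(sessions, roster, (d0, dt.date(2021, 7, 31)))
print(f"{summary.n_sessions} sessions, {summary.distinct_chimps} chimp(s) trained, "
      f"{summary.colony_fraction:.0%} of the colony engaged")

# 31 asked-days in July: complied on 23, plus 3 weather days (excluded)
shifts = []
for day in range(31):
    date = dt.date(2021, 7, 1) + dt.timedelta(days=day)
    weather = day in (10, 11, 12)
    shifts.append(ShiftRecord(date, "G1", "shifter1", "shift outside",
                              weather_excluded=weather, alternate_goal=False,
                              complied={"Latoya": day % 4 != 0}))

pct = shifting_compliance(shifts, "Latoya", month=(2021, 7))
print(f"Latoya July 2021 shifting compliance: {pct:.0f}% "
      "(weather days leave the denominator)")
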