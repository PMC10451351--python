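"""Score a multi-assessor wellness survey and classify the action band.

Three assessors (one per animal-care department) each rate ten
behavioral parameters 0-3 for one chimp.  Per parameter the scores are
averaged; the weighted means sum to a 0-30 total, and the total maps to
an action band: routine (<12), elevated (12-29), or critical (>29).
"""

import datetime as dt

from chimpwelfare import WellnessResponse, score_survey, schedule_wellness
from chimpwelfare.core import ChimpProfile
from chimpwelfare.defaults import WELLNESS_PARAMETERS

date = dt.date(2022, 3, 15)
zeros = {p: 0 for p in WELLNESS_PARAMETERS}

responses = [
    WellnessResponse("Kasey", "rj", "veterinary", date, {**zeros, "ABN": 2, "WOU": 2}),
    WellnessResponse("Kasey", "af", "behavior", date, {**zeros, "ABN": 1, "WOU": 2, "SCO": 1}),
    WellnessResponse("Kasey", "lk", "husbandry", date, {**zeros, "ABN": 2, "WOU": 1}),
]

score = score_survey(responses)
print(f"total wellness score: {score.total:.2f}  band: {score.band}")
for p in ("ABN", "WOU", "SCO"):
    print(f"  {p} weighted mean: {score.per_parameter_mean[p]:.2f}")

# A total well under 12 keeps the chimp on regular quarterly monitoring;
# the per-parameter means show where the (mild) concern concentrates.

roster = [ChimpProfile("Kasey", "Kasey", "M", dt.date(1988, 1, 1), "G1")]
plan = schedule_wellness(roster, 2022)
print("planned 2022 surveys:", ", ".join(d.isoformat() for d in plan["Kasey"]))
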