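"""Zone-weighted hair-loss scoring and the 25% significance threshold.

Observers score each of seven body zones on the five-point percent
scale {0, 25, 50, 75, 100}; the total is the zone scores weighted by
each zone's share of ideal hair surface area.  At 25% or more total
loss, monitoring escalates to three observers every four months.
"""

import datetime as dt

from chimpwelfare import HairLossSurvey, hairloss_trajectory, total_hair_loss
from chimpwelfare.hairloss import default_zone_map, zone_weights_from_grid

zm = default_zone_map()
print("zone weights:", {z: round(w, 3) for z, w in zm.weights.items()})

# loss concentrated on arms (D, E), back (C) and head (A)
march = HairLossSurvey("Bischk", dt.date(2022, 3, 1), "obs1",
                       {"A": 25, "B": 0, "C": 25, "D": 50, "E": 50, "F": 0, "G": 0})
july = HairLossSurvey("Bischk", dt.date(2022, 7, 1), "obs1",
                      {"A": 25, "B": 0, "C": 25, "D": 25, "E": 25, "F": 0, "G": 0})

results = [total_hair_loss(s, zm) for s in (march, july)]
for r in results:
    print(f"{r.date}: total hair loss {r.total_pct:.1f}%  significant={r.significant}")

series, deltas = hairloss_trajectory(results, "Bischk")
print("between-survey change (pct points):", [round(d, 1) for d in deltas])

# Weights can also be derived from a grid mask over a body diagram:
custom = zone_weights_from_grid({"A": 800, "B": 1800, "C": 2200, "D": 1400,
                                 "E": 1400, "F": 1200, "G": 1200})
print("grid-derived weight for zone C:", round(custom.weights["C"], 3))
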