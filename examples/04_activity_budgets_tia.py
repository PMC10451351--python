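"""Activity budgets from focal sessions, TIA triggers, and pre/post deltas.

A Targeted Individual Assessment (TIA) runs daily 15-minute continuous
focal observations on a chimp of concern.  An abnormal-behavior share
strictly above 10% of the budget triggers assessment; budgets before and
after an intervention are compared category by category.
"""

import datetime as dt

from chimpwelfare import (
    ObservationRecord,
    budget_from_focal,
    evaluate_tia_triggers,
    pre_post_comparison,
    sms_schedule,
    assign_observation_slots,
)

t0 = dt.datetime(2022, 5, 1, 8, 0)


def session(day, picking_s):
    """One 900 s focal: wound-picking (abnormal) plus rest."""
    start = t0 + dt.timedelta(days=day)
    records = []
    if picking_s:
        records.append(ObservationRecord(start, "obs", "Kasey", "wound_pick",
                                         "continuous", duration_s=float(picking_s)))
    records.append(ObservationRecord(start + dt.timedelta(seconds=picking_s), "obs",
                                     "Kasey", "rest", "continuous",
                                     duration_s=float(900 - picking_s)))
    return records


pre_records = [r for d in range(14) for r in session(d, picking_s=110)]
post_records = [r for d in range(14) for r in session(d, picking_s=5)]

pre = budget_from_focal(pre_records, "Kasey")
post = budget_from_focal(post_records, "Kasey")
print(f"pre-intervention abnormal share:  {pre.pct['abnormal']:.2f}%")
print(f"post-intervention abnormal share: {post.pct['abnormal']:.2f}%")

triggers = evaluate_tia_triggers("Kasey", budget=pre)
print("TIA triggers on the pre budget:", [t.cause for t in triggers])
# 12.2% > 10% fires the abnormal-budget trigger; the post budget would not.

deltas = pre_post_comparison(pre, post)
print(f"abnormal delta: {deltas['abnormal']:+.2f} pct points "
      f"(deltas sum to {sum(deltas.values()):.1e})")

# The SMS scheduler plans routine observation campaigns by reason:
schedule = sms_schedule("Post-Social Integration")
slots = assign_observation_slots(schedule, "Kasey", dt.date(2022, 6, 1), seed=4)
print(f"{schedule.reason}: {schedule.n_observations} observations over "
      f"{schedule.duration_days} days; first slot {slots[0]['date']} "
      f"{slots[0]['block_start']}-{slots[0]['block_end']}")
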