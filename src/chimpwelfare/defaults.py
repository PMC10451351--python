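"""Packaged default configurations.

The default ethogram carries 34 instantaneous behavior codes and 6
all-occurrence codes spread over the nine behavioral categories used for
activity budgets.  The code names here are illustrative defaults; real
deployments load their own ethogram from YAML/JSON config.

The default body-zone map divides the chimpanzee body into seven zones
(A-G) with surface-area weights summing to 1.  The weights are an
illustrative fixture; sites deriving weights from their own grid masks
should use :func:`chimpwelfare.hairloss.zone_weights_from_grid`.
"""

BEHAVIOR_CATEGORIES = (
    "inactive",
    "food_drink",
    "self_directed",
    "locomotion",
    "affiliative",
    "abnormal",
    "aggressive",
    "sexual",
    "other",
)

# 34 instantaneous codes, code -> category
DEFAULT_INSTANTANEOUS = {
    "rest": "inactive",
    "sleep": "inactive",
    "sit_idle": "inactive",
    "lie_down": "inactive",
    "feed": "food_drink",
    "drink": "food_drink",
    "forage": "food_drink",
    "process_food": "food_drink",
    "self_groom": "self_directed",
    "self_scratch": "self_directed",
    "self_touch": "self_directed",
    "walk": "locomotion",
    "climb": "locomotion",
    "brachiate": "locomotion",
    "run": "locomotion",
    "groom_other": "affiliative",
    "play_social": "affiliative",
    "embrace": "affiliative",
    "touch_other": "affiliative",
    "food_share": "affiliative",
    "rock": "abnormal",
    "pace": "abnormal",
    "hair_pluck": "abnormal",
    "wound_pick": "abnormal",
    "regurgitate": "abnormal",
    "overgroom": "abnormal",
    "display": "aggressive",
    "chase": "aggressive",
    "hit": "aggressive",
    "threat": "aggressive",
    "mount": "sexual",
    "inspect_genital": "sexual",
    "object_play": "other",
    "tool_use": "other",
}

# 6 all-occurrence codes (rare, event-counted behaviors), code -> category
DEFAULT_ALL_OCCURRENCE = {
    "scream": "other",
    "contact_aggression": "aggressive",
    "charge_display": "aggressive",
    "copulation": "sexual",
    "pant_grunt": "affiliative",
    "reassurance": "affiliative",
}

# Ten wellness survey parameters, each scored 0-3 by each assessor.
WELLNESS_PARAMETERS = (
    "ABN",  # abnormal behavior
    "LOC",  # locomotion
    "ACS",  # access to food/water
    "HAI",  # human-animal interaction
    "COT",  # coat appearance
    "SAG",  # self-aggression
    "SIA",  # social interaction
    "SCO",  # staff concern
    "ENR",  # enrichment/medication/reinforcer acceptance
    "WOU",  # wounds
)

# Seven body zones with fractions of ideal hair surface area.
DEFAULT_ZONE_WEIGHTS = {
    "A": 0.08,  # head
    "B": 0.18,  # chest / torso front
    "C": 0.22,  # back
    "D": 0.14,  # left arm
    "E": 0.14,  # right arm
    "F": 0.12,  # left leg
    "G": 0.12,  # right leg
}

# Wound concern criteria over a rolling 14-day window.
DEFAULT_WOUND_CRITERIA = {
    "any_grade_total": 10,
    "grade3_count": 4,
    "grade4_count": 3,
    "grade5_count": 1,
}

# Social Monitoring System: reason -> (duration in days, observations per chimp).
SMS_SCHEDULE_TABLE = {
    "Post-Social Integration": (90, 13),
    "Separation from Group": (90, 13),
    "Yearly Check-In": (42, 6),
    "Wounding/Aggression/Welfare": (42, 6),
    "Considered for Integration": (42, 6),
    "Release to Novel Area": (28, 4),
    "New Arrival": (90, 13),
    "Pre-Social Integration": (42, 6),
    "Wounding/Aggression Check-In": (42, 6),
    "New Arrival 6 Month Check In": (28, 4),
    "Integration Check In 6 Months": (28, 4),
    "Integration Check-In 1 Year": (28, 4),
    "Death of a Group Member": (42, 6),
}

# Daily observation time blocks (facility-local, timezone-naive).
OBSERVATION_TIME_BLOCKS = (
    ("07:30", "10:30"),
    ("10:30", "12:30"),
    ("13:30", "15:30"),
)
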