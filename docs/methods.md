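# Methods

`chimpwelfare` implements seven behavioral-welfare metric protocols for
managed chimpanzee colonies as one tested library, exercised end to end
on a seeded synthetic colony simulator. This note documents the models,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic data do and do not show.

## Composite wellness score

Ten parameters — abnormal behavior (ABN), locomotion (LOC), food/water
access (ACS), human-animal interaction (HAI), coat (COT),
self-aggression (SAG), social interaction (SIA), staff concern (SCO),
enrichment acceptance (ENR), wounds (WOU) — are each rated 0–3 by
multiple assessors drawn from the husbandry, behavior, and veterinary
teams. The score is

    Total = Σ_p w_p · mean_assessors(raw_p),

with unit default weights `w_p = 1`, giving a 0–30 scale (10 parameters
× max raw 3). Custom weights are allowed; the validator warns when the
attainable maximum is not 30, because the action bands assume that
scale.

**Action bands.** The protocol's published bands ("0–12", "12–29",
">30") overlap at 12 and leave (29, 30] unassigned; a score above 30 is
unattainable on the scale, so a literal ">30" critical band could never
fire. Both ambiguities are resolved toward concern: routine is the
half-open interval [0, 12), elevated is [12, 29], and everything above
29 is critical. The boundary 12 therefore escalates, and the nominal
gap (29, 30] escalates. This is a deliberate, documented resolution of
an inconsistent source rule, not a tunable.

A chimp is "of concern" on a parameter when any weighted per-parameter
mean in the period reaches a cutoff (default 1.0, configurable — the
source protocol does not define this predicate). Scheduling plans four
surveys per chimp per year, mid-quarter (Feb/May/Aug/Nov 15) so each
lands in a distinct season.

## Wound surveillance

Wounds are graded 1–5 (superficial scratch → gaping/missing body part).
The log records only a wound's initial occurrence and strict-grade
escalations, so counting always deduplicates by `wound_id` at the
maximum grade among events inside the window under evaluation.

Concern criteria over a rolling 14-day window (both endpoints
inclusive): ≥10 wounds of any grade, ≥4 grade-3, ≥3 grade-4, or ≥1
grade-5. Grade-specific criteria count wounds of exactly that grade;
a grade-4 wound does not count toward the grade-3 criterion (higher
grades carry stricter criteria of their own).

**Window anchoring.** Candidate windows are anchored with their start
*or their end* at an event date. End anchors are necessary, not a
convenience: exact-grade counts are not monotone as a window slides,
because an escalation entering the window moves a wound out of its
previous grade bucket. For any window W, the window ending at the last
event in W contains every event of W, and any extra earlier events it
picks up can only add wounds to buckets (an earlier event of an
already-counted wound has a strictly lower grade, leaving the in-window
maximum unchanged) — so the anchored family dominates all real-valued
anchors. The property suite verifies this against brute-force
enumeration of every calendar-day window.

Flags deduplicate to one per (chimp, criterion) per contiguous episode
(successive satisfying anchors less than 14 days apart), reported at
the earliest satisfying window, so a single wounding episode does not
flood weekly summaries. Adding events never removes a flag.

## Hair loss

Seven body zones (A–G) carry weights equal to their fraction of ideal
hair surface area; `zone_weights_from_grid` derives weights from
grid-cell counts over a body diagram (hairless parts excluded by the
mask, not by runtime logic). The packaged default weights (A 0.08,
B 0.18, C 0.22, D/E 0.14, F/G 0.12) are an illustrative fixture, fully
configurable. Observers score each zone on {0, 25, 50, 75, 100};
off-scale observed values snap to the nearest point with exact
midpoints rounding up (toward concern). Total loss is Σ_z w_z·s_z,
linear and bounded by the zone-score extremes. Significance is
`total ≥ 25%`, inclusive: monitoring escalates from one colony sweep
per 15 months to an occasion every 4 months staffed by three distinct
observers. New arrivals get an immediate baseline survey.

## Activity budgets, SMS scheduler, TIA triggers

Instantaneous scan proportions estimate time-budget fractions
(multinomial sampling, standard error ∝ n^(−1/2)); all-occurrence
records never enter scan denominators and are reported as events per
observation hour. Continuous focal budgets weight by recorded
durations, with overlapping intervals rejected. Group budgets pool
scans over members (an equal-weight-per-individual alternative can be
had by averaging per-chimp budgets; pooling is the default because
observation effort is near-uniform by design).

The Social Monitoring System scheduler is a closed table of 13
observation reasons → (duration, observations per chimp), e.g.
Post-Social Integration → 13 observations over 3 months, Yearly
Check-In → 6 over 6 weeks, Release to Novel Area → 4 over 4 weeks.
Slot assignment splits the duration into equal segments, one
observation day uniform within each, and a uniform choice among the
three daily observation blocks (07:30–10:30, 10:30–12:30, 13:30–15:30);
fully deterministic given a seed. Months are encoded as 30 days and
weeks as 7 for duration arithmetic.

TIA triggers are four independent causes: a high-priority abnormal
behavior report, any wound concern flag, an abnormal-category budget
share strictly greater than 10% (strict, per the protocol's "more than
10%"), or an externally filed notable-change report (no detection rule
is inferred — "notable" is the reporter's judgment). The TIA template
is two weeks of daily 15-minute focals pre-intervention and the same
after, with counts configurable since real assessments deviate.
Pre/post comparison is a per-category difference; deltas sum to zero by
construction.

## Nearest night neighbors

One record per chimp per night: location (indoor/outdoor) and nearest
neighbor with proximity class (contact, arm's reach, within 3 m,
outside 3 m, or no neighbor in shared space). Pair matrices count
nights per unordered pair; a night counts once even when both members
name each other, since edge weights mean *nights*, not mentions.
Stratified matrices are per-class by default (matching separate
contact / arm's-reach / within-3 m panels) with a cumulative option
that nests: contact ≤ arm's-reach-or-closer ≤ all, elementwise.
Records with proximity outside 3 m enter only the "all" matrix;
no-neighbor records enter none. Unobserved nights are simply missing
and leave denominators. Layout is seeded force-directed
(Fruchterman–Reingold, fixed iterations) with pair counts as attraction
weights, so stronger pairs sit closer in expectation; the property is
verified on a weighted line graph rather than assumed.

## PRT and shifting analytics

Session keys are the separator-escaped concatenation of (date, time,
trainer, chimp) — deterministic and injective by construction.
Cue responses use the protocol's 1–3 scale. A `co_trainers` field
records mentor/mentee sessions. Shifting compliance for a chimp-month
is 100 × complied / eligible asked-days, where weather-excluded days
and alternate-goal days leave the denominator and a chimp absent from a
record's compliance map was not asked; zero eligible days yields an
explicit undefined (`None`), never 0%. Group compliance defaults to
"every asked member complied", with a pluggable predicate for
individual alternative definitions (e.g. calm-behavior criteria).

## Synthetic colony simulator

The simulator generates every record stream from known ground truth,
deterministic given a master seed; each stream has its own child
generator (`SeedSequence.spawn`), so adding a stream never perturbs the
others. Defaults (all overridable):

| quantity | default | basis |
|---|---|---|
| behavior mixture | inactive 51.17%, food/drink 16.24%, self-directed 10.57%, locomotion 9.07%, affiliative 6.68%, abnormal 2.0%, aggressive 1.5%, sexual 1.0%, other 1.77% | inactive-dominant colony budget typical of sanctuary chimpanzees; illustrative, not fitted |
| wound rate | 0.01 /chimp-day | of the order of a few wounds per chimp-year |
| severity distribution | (0.5162, 0.3006, 0.1361, 0.0350, 0.0121) | superficial-dominant; grades 4+5 jointly ≈4.7%, split 3.50/1.21 as a documented choice |
| escalation probability | 0.05 | rare worsening within a week |
| wellness raw-score distribution | P(0..3) = (0.90, 0.07, 0.02, 0.01) | colony-mean total ≈1.4, a healthy colony |
| no-neighbor probability | 0.10; indoor probability 0.90 | most chimps sleep indoors near a neighbor |
| planted pair weight | 6 × baseline preference | clearly strongest bond per group |
| shift compliance | Bernoulli(0.8) per chimp-day | compliant but imperfect |

What the simulator does **not** emulate: observer disagreement beyond
iid noise, seasonal and enclosure effects on behavior and hair loss,
demographic change (births, deaths, transfers), wound healing, social
contagion of behaviors, and within-night neighbor turnover. Passing
recovery tests therefore demonstrates estimator correctness under the
stated sampling models — not robustness to the structured biases of
real observational data.

`recovery_report` compares severity estimates against *initial* grades:
escalations shift observed mass upward by protocol design, which is
behavior, not estimation error.

## Record IO and name validation

Records exchange as UTF-8 CSV with a mandatory header (or JSON arrays
mirroring the columns 1:1); dates are ISO-8601, timezone-naive facility
time. Malformed rows either abort with a line number or are collected
under a skip policy. Because misspelled chimp names silently corrupt
counts, every name field is validated against the roster
(case-insensitive by default) and unknown names are reported with the
nearest roster name by Levenshtein distance, ties alphabetical —
report content, never an exception.

## Test problem sizes

The suites run at deliberately modest sizes chosen to make the
statistical assertions sharp: oracle equivalence on 200 random wound
logs (≤50 events, 2–3 chimps) and 100 random colonies (≤10 chimps × ≤30
nights); mixture recovery at 20,000 scans against 3 multinomial
standard errors; planted-pair recovery over 100 seeds at 200 nights
(≥95 successes required); noiseless compliance recovered exactly. The
full suite completes in well under a minute on one CPU.

## Known limitations

* The critical wellness band's literal ">30" rule is unreachable on the
  0–30 scale; the implemented >29 boundary is this package's documented
  resolution.
* Wound body-location coding, healing progress, and non-wound injuries
  are out of scope (the protocol assigns them to veterinary systems).
* Sociograms carry no directed or behavioral information — nearest
  nights only; centrality and community statistics are deliberately not
  provided.
* The default ethogram's 34 + 6 code names are package-invented
  placeholders for a facility's own configured ethogram; only the
  nine-category layer is semantically load-bearing.
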