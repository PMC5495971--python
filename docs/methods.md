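# Methods

This note documents the models, rules and numerical choices behind
`glucolog`, and what the synthetic generator does and does not emulate.

## Domain rules

**Glucose unit and plausibility.** Everything internal is mmol/L; an input
option divides mg/dL by 18.016.  A reading outside (0, 40) mmol/L is
physiologically impossible for a meter and is *quarantined* (kept with its
line number and the violated invariant), never silently dropped —
clinic-style data must stay auditable.  Timestamps are naive, at minute
resolution; the data model assumes a single locale.

**Target band.** The in-range band is closed (boundary values in target):
the patient-positive reading of an ambiguous boundary.  Context-specific
override bands are supported.

**Device merging.** A pump often mirrors the meter it is linked to, so a
clinic download can contain the same finger stick twice.  Two readings
within 1 minute and 0.1 mmol/L (both configurable) collapse into one,
keeping meter over pump over manual.  Merging is idempotent under the
exact-duplicate policy.

**Analysis window.** "The previous 50 days" anchored at a clinic date is
half-open: `end − days < t ≤ end`, keeping download-day readings and
excluding the reading exactly 50 days earlier.

**Trend detection.** Each context's chronological subsequence is scanned
independently; a maximal run of ≥ 3 readings out of range in one
direction is exactly one event (no overlapping sub-runs).  Consecutiveness
crosses days by construction — three successive dinners count.  A mixed
high/low run is not one actionable phenomenon, so an opposite-direction
reading breaks a run and starts a new one.  A later in-target reading in
the same context *expires* an unresolved trend; this gives "days with no
active trend" (the trend-avoidance reward) a well-defined complement.
Resolution requires a non-empty cause; re-resolving is a state error.

**Reward points.** Per calendar day: `min(n_readings, 5) ×
points_per_reading`, plus `points_in_target` per in-target reading
(uncapped), plus a trend-free-day bonus on days with ≥ 1 reading and no
active trend, plus a resolution bonus per resolved trend.  The magnitudes
(1/1/2/10) are configuration, with the resolution bonus deliberately
largest; a day on which a trend is detected and resolved still counts as a
trend-active day.  Leaderboard ranking is competition style (1, 1, 3) on
pseudonymized ids.

**Engagement.** With upload fraction f = upload_days/total_days:
very_low f < 1/14, low 1/14 ≤ f < 1/7, moderate 1/7 ≤ f < 3/7, high
f ≥ 3/7.  Boundaries are lower-inclusive because the level definitions
phrase upper bounds as "less than"; the four levels partition [0, 1].

**Mild hypoglycemia episodes.** Readings below 3.4 mmol/L map to
clock-hour slots; identical or adjacent slots link, and each connected
chain is one episode, so a prolonged low with repeated confirmation sticks
is counted once.  Chaining is transitive by default (02:xx–03:xx–04:xx is
one episode); a non-transitive variant (an episode spans only the anchor
slot and the next hour) sits behind a flag because either reading of
"same or consecutive-hour timeslots" is defensible.

**SMBG frequency.** Response groups take precedence: a reading below
4.1 or above 17.9 mmol/L that is not already absorbed anchors a group
that greedily absorbs everything in the following 2 hours (absorbed
readings cannot anchor — "in response to an *initial* low" names one
trigger).  Remaining readings sharing a clock hour form one group.  Daily
frequency is groups per window day, divided by the participant-estimated
availability fraction.  Response grouping is applied to SMBG counting
only, not to hypoglycemia episodes.

**Severe hypoglycemia** is interview-based only: assisted by another
person AND (glucose < 2.8 mmol/L OR symptom reversal with treatment).
Nothing is inferred from meter traces.

**Questionnaires.** Only ids, scales and arithmetic are shipped (the
instruments are licensed).  SCI: mean of non-NA items × 10, which maps the
1–5 item scale onto the published 10–50 range and is invariant to which
items are NA.  DQOLY: subscale sums of reverse-coded items (0–4 scales
inverted as 4−x; the single-item Health Perception subscale, 1–4, as 5−x);
item counts per subscale are derived from the published subscale ranges
and the default item-to-subscale mapping is user-replaceable, since the
authoritative mapping is not public.  DFRQ: straight sums (17 items, 1–3;
total 17–51).

## Synthetic generator

The generator is behavioural, not physiological — it emulates what
downloaded data look like, not insulin–glucose dynamics.

- **Values.** Per-context glucose is log-normal (strictly positive,
  right-skewed like meter data).  (μ, σ) are solved numerically from two
  constraints: P(X < 3.4) = `p_mild_low` and P(4 ≤ X ≤ 10) =
  `p_in_target`.  The constraint system can have two roots; the wider one
  is taken (glucose in poorly controlled T1D has a large CV; the narrow
  root would park the whole distribution just above the hypoglycemia
  threshold).  Each participant's μ is then shifted so their long-run mean
  glucose matches their screening HbA1c through the eAG relation
  HbA1c = (mean_bg + 2.59)/1.59.  `p_in_target = 1` degenerates to uniform
  sampling inside the band.
- **Timing.** Each day each context is tested independently with
  probability `smbg_rate × mix`, at a context-typical hour (±10 min).
  The six context hours are ≥ 2.5 h apart, so distinct contexts never
  share an hour slot or fall inside one another's 2-hour response window —
  the generative group rate therefore equals the test rate, which is what
  the Monte-Carlo recovery tests exploit.
- **Defaults as study conditions.** 4 tests/day at enrollment
  (intervention; 3.6 usual care), `p_in_target` 0.45 and `p_mild_low`
  0.04 (consistent with screening HbA1c near 9%), ~2 injected trends per
  30 days, adherence half-life 1900 days (the observed ~12% decline in
  daily SMBG over 12 months), median upload probability 0.08 with a
  between-participant log-SD of 1.2 — which reproduces the heavily skewed
  engagement profile (roughly 40/25/25/10% across very-low → high).
  A shared activity multiplier (log-SD 0.3) scales both testing and
  uploads, giving the positive engagement–SMBG coupling seen in usage
  data.
- **Trend injection** replaces a run of 3–5 same-context days with draws
  from the participant's *own* upper tail (truncated above the band), so
  injected runs scale with any intervention effect instead of diluting it.
- **Cohorts.** Strata (pump/injection × site A/B) are drawn 50/50;
  within each stratum arms are assigned in shuffled blocks of 4 or 6, so
  per-stratum imbalance is at most 5.  Screening HbA1c is uniform on
  [8.0, 10.5]%, ages uniform on [11, 16].  Visits at months {0, 3, 6, 9,
  12}; each visit cuts the trailing 50-day window and computes the
  outcome battery through the same code a real download would use.
  Visit HbA1c = eAG(trailing 90-day mean glucose) + N(0, 0.3²) noise.
- **Arm effects.** `delta_hba1c_slope` is defined on the *measured* HbA1c
  scale: because a visit HbA1c reflects the trailing 90-day glucose mean,
  the instantaneous glucose target jumps by slope×45/365 at onset and
  then ramps, so the measured 12-month change equals the injected slope
  while baseline stays untouched.  `delta_smbg` adds to the daily testing
  rate after onset.
- **Determinism.** The cohort seed spawns one named substream per
  participant (`default_rng([seed, index])`); identical seeds give
  byte-identical outputs.

What it does **not** emulate: meal-driven within-day correlation,
insulin dosing feedback, seasonal effects, device clock drift, or
informative missingness (availability hiding is random).  Passing tests
therefore demonstrate the correctness of the measurement and analysis
machinery under a plausible data-generating process, not clinical
realism of any particular trajectory.

## Trial statistics

- **Sample size** uses the standard normal-quantile two-sample formula
  (see README).  At the design's default SD (0.75%) the Monte-Carlo
  power of the pooled t-test at the returned n = 36 meets the nominal 80%
  within 2 points.  Known limitation: the z-formula ignores the t
  correction, so at small n (e.g. SD 0.55 → n = 19) the t-test's true
  power is ≈ 0.778, a fraction of a point below nominal; the
  assumption-matched known-variance z oracle agrees with the formula
  across the whole 0.50–0.75% SD range.
- **Mixed model.** One scalar random intercept per participant; REML by
  profiling λ = σ_b²/σ_e² (bounded search on log λ, explicit λ = 0
  boundary check; per-group rank-one inversion keeps each evaluation
  O(n p²)).  Time is categorical visit (5 levels) and the headline test
  is the joint F on the group×visit terms with containment denominator
  df (N − participants − within-effect count), which is the exact
  split-plot test on balanced compound-symmetric data; the empirical
  type-I error at the trial's scale (46/arm) is within binomial noise of
  5% over 2000 null replicates.  At very small sizes (~15/arm) the Wald
  F is mildly anticonservative (~6%).  Missing visits simply contribute
  no rows.
- **Baseline balance**: pooled t-tests for continuous variables, Pearson
  chi-square without continuity correction for the stratification
  factors (a Yates-corrected variant is exposed for 2×2 tables).
- **Skewed counts** (mild hypoglycemia) are analyzed by the same linear
  model, relying on its robustness at this sample size; a log1p
  sensitivity transform can be applied to the outcome column upstream.
- **Subgroup analysis** (daily SMBG ≥ 5 at 12 months, boundary
  inclusive): within-subgroup paired baseline-to-12-month comparison and
  between-subgroup per-visit t-tests.  The recovery experiments measure
  the arm effect as the between-arm difference of paired changes
  (difference-in-differences), which cancels the small common upward
  drift that trend injection introduces as natural testing decays.
- **Engagement association**: ordinal trend regression of participant
  mean SMBG on engagement level (0–3); a single occupied level is
  reported as undefined rather than tested.

## Problem sizes in the checks

The property suites run 1000 randomized windows/sequences against
brute-force oracles (union-find episode grouping, exhaustive maximal-run
scan), 2000 null replicates for test calibration at the trial's own arm
size, 5000 replicates for power checks, and 40–50 small cohorts
(8 vs 5 participants after trimming, the published subgroup sizes) for
the 0.58%/year recovery experiment.
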