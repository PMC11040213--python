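# Methods

## Problem and model

`pregepisodes` identifies pregnancy episodes in longitudinal
administrative claims — person-level streams of dated diagnosis,
procedure and drug codes — and estimates each episode's last menstrual
period (LMP), the conventional pregnancy start date. Claims record
healthcare contacts, not pregnancies: a single pregnancy produces many
related claims, outcomes are sometimes cross-coded (e.g. a stillbirth
accompanied by delivery claims), and the LMP is never recorded directly.
The algorithm is a deterministic rule pipeline:

1. **Outcome detection.** Delivery events come from delivery *procedure*
   codes; abortion and stillbirth events from *diagnosis* codes.
   Abortion procedure codes deliberately do not assert an outcome: they
   are common in ambiguous contexts and serve only as gestational-age
   (GA) markers. Events are restricted to women of childbearing age
   (completed years 12–49, inclusive, at the event).
2. **Clustering.** Per person and outcome type, events chain into one
   episode while consecutive events are closer than the same-episode gap
   (defaults: 168 days for delivery and stillbirth, 56 for abortion).
   The earliest claim anchors the episode's outcome date.
3. **Hierarchy resolution.** Overlapping episodes of different types are
   resolved by the priority order stillbirth > delivery > abortion
   (stillbirths can legitimately co-occur with delivery claims, and
   abortion coding is the least specific). The lower-ranked episode of
   any pair whose outcome dates are closer than the cross-outcome
   conflict window is marked eliminated; ranks are processed top-down so
   an episode eliminated by a higher rank cannot itself eliminate
   anything. Eliminated episodes are retained with status for audit.
4. **LMP estimation.** GA-informative markers imply an LMP as
   `claim_date − midpoint(GA window)`. Sonography tiers are prioritised
   narrowest-range-first: second/third-trimester target scan, first-
   trimester target scan, first-trimester routine, second/third-
   trimester routine. Preterm diagnoses with a specified GA outrank
   unspecified ones; an unspecified preterm diagnosis implies a fixed GA
   of 245 days (35 weeks) at the outcome. Deliveries may use sonography
   and preterm markers, abortions abortion-procedure and sonography
   markers, stillbirths sonography only. Among surviving markers the
   latest implied LMP (smallest GA at outcome) wins; residual ties go to
   the smallest GA at the claim date. Without any marker, a fixed GA is
   subtracted: 273 days (39 weeks) for delivery, 196 (28 weeks) for
   stillbirth, 70 (10 weeks) for abortion.
5. **Refinement.** If an episode's LMP falls before the previous kept
   outcome plus the retry period (28 days), it is pushed to exactly that
   date, cascading left-to-right. Then GA bounds apply: stillbirths
   under 140 days (20 weeks) are reclassified as abortions; deliveries
   under 140 days and any episode over 294 days (42 weeks) are excluded
   as miscoded; remaining deliveries split at 259 days (37 weeks) into
   preterm and full-term. Abortions with at least one induced-abortion
   code inside `[LMP, outcome + abortion gap)` are induced, otherwise
   spontaneous.
6. **Reporting.** Prevalence of the five final outcome classes with
   binomial confidence intervals and GA summaries (completed weeks),
   the LMP-method × outcome cross-table, optional calendar strata, and
   drug-exposure trajectories over preconception quarters (four 90-day
   bins before the LMP) and pregnancy periods (0–7 weeks, trimesters at
   0–98, 98–196, 196–outcome days). Exposure uses two definitions:
   primary (>1 prescription in the window) and sensitivity (≥1).

## Parameters that matter

All tunables live in `AlgorithmParams` (YAML-overridable; the shipped
`default_params.yaml` documents each field):

| parameter | default | why |
|---|---|---|
| hierarchy | stillbirth > delivery > abortion | outcome-code validity ordering |
| same_episode_gap_days | 168/168/56 | clinically plausible claim span of one episode |
| cross_outcome_conflict_days | min of the two gaps | conservative conflict window |
| retry_period_days | 28 | minimum interval from outcome to next conception |
| outcome_specific_ga_days | 273/196/70 | fixed 39/28/10-week fallbacks |
| unspecified_preterm_ga_days | 245 | 35-week fixed GA for unspecified preterm codes |
| preterm_cutoff / max_ga / min_delivery / stillbirth_reclass | 259/294/140/140 | 37/42/20/20-week plausibility rules |
| childbearing_age | [12, 49] | algorithm-level inclusion range |
| exposure_min_prescriptions | 2 | the “more than one prescription” primary definition |

The clustering gaps, conflict windows and retry period are conventions
of the hierarchy-algorithm family this pipeline belongs to rather than
universal constants; they should be revisited per claims dialect.

## Numerical and design choices

- All dates are ISO calendar dates; durations are integer days;
  intervals are half-open `[start, end)` unless a rule is explicitly
  inclusive (age bounds; the end of pregnancy for exposure windows).
  GA-window midpoints are `floor((min+max)/2)`.
- **Marker plausibility corridor.** A marker is admitted to an episode
  only if its claim date lies within `[outcome − 294 d, outcome]` *and*
  its implied GA at the outcome lies in `[1, 294]` days. The corridor is
  this package's construction: something must decide which of a woman's
  claims belong to which pregnancy, and without the claim-date clause a
  fixed-offset unspecified-preterm claim from a previous pregnancy would
  always pass (its implied GA is 245 by construction, independent of the
  claim date).
- **Tier strictness.** Whether sonography tier priority strictly
  dominates the latest-LMP rule, or merely orders markers before it, is
  genuinely open; the default (`tier_strict: true`) applies the tier
  filter first. The alternative is one config switch away.
- **Retry trigger.** The published wording ("LMP earlier than the
  previous outcome date") suggests a strict-overlap trigger, but the
  adjustment target (previous outcome + retry period) then leaves
  unadjusted episodes that start inside the retry period. The default
  (`retry_trigger: separated`) fires whenever the LMP falls within the
  retry period of the previous outcome, so kept episodes are always
  separated by at least the retry period; `strict` reproduces the
  literal wording.
- **Abortion GA cap.** Kept abortions are capped at 140 days; an
  abortion dated to a longer gestation (possible via a stale
  second/third-trimester sonogram) is excluded as overlong rather than
  silently kept, so every kept episode respects its class's GA bounds.
  The minimum abortion GA (21 days) is a validity convention of the
  reporting layer, not an exclusion rule.
- Ties everywhere break deterministically (code string, category order,
  claim date), so a rerun on identical inputs is byte-identical.

## The synthetic cohort

The generator (`pregepisodes.synthetic`) is the test harness: it draws
women, true pregnancies and claims with known ground truth. Defaults:

- Pregnancies per woman ~ Poisson(1.65), capped at 6; LMPs in
  2005–2017 within a 2003–2018 observation span; maternal age 18–35 at
  the first LMP so all outcomes fall inside the childbearing range.
- Outcome mix: 56% full-term, 11% preterm, 2% stillbirth, 28%
  spontaneous and 3% induced abortion.
- GA per outcome from truncated normals (days): full-term N(272, 7) on
  [259, 294]; preterm N(238, 21) on [140, 258]; stillbirth N(189, 17) on
  [140, 238]; abortion N(60, 17) on [21, 140]. These are simulator
  conventions chosen to respect the per-class GA bounds, not empirical
  claims.
- Marker emission per category is Bernoulli with an era switch at
  2016-01-01 (emulating a reimbursement expansion for prenatal
  sonography and GA-specific preterm codes: e.g. routine sonography
  0.10 → 0.65, GA-specified preterm 0.05 → 0.70).
- Noise: per-claim duplication, cross-coded lower-rank outcome claims
  injected near delivery/stillbirth outcomes (each labelled in the
  truth), and orphan claims with codes unknown to the codelist.
- Prescriptions: per drug class and window, a Bernoulli(p) decision to
  emit exactly k prescriptions uniformly inside the window (defaults
  shape a declining trajectory from preconception into pregnancy).

Two idealisations make noise-free truth exactly recoverable and are
*not* features of real claims: GA-window marker claims are dated
`true_LMP + midpoint`, so midpoint subtraction is exact rather than
merely unbiased; and consecutive pregnancies are separated by the retry
period plus 360–720 days, which keeps each pregnancy's markers and
prescriptions outside its neighbours' plausibility corridors and
exposure windows. Passing recovery tests therefore demonstrates that
the pipeline's logic is faithful to its rules, not that real-world
accuracy is 100%: with real data, marker dates scatter within their GA
windows, short interpregnancy intervals create genuine attribution
ambiguity, and code usage differs by site and era. The era-dependent
emission defaults deliberately reproduce one known consequence: before
the era cut, markerless true preterms are dated by the 39-week fallback
and counted as full-term, understating preterm prevalence.

## Validation harness

Unit and property tests compare clustering, hierarchy resolution and
marker selection against independent brute-force formulations on
randomized instances, and check the rule constants operationally
(fixed-subtraction dates, boundary-exact GA splits, retry arithmetic).
Cohort-level tests run the full pipeline on seeded synthetic cohorts:
a noise-free, fully GA-informative cohort of 2,000 women (~3,300
episodes) for exact recovery, a 1,000-woman noisy cohort (30% duplicate
claims, 5% cross-coded outcomes) for invariant robustness and conflict
elimination, and small targeted scenarios for exposure arithmetic.
`scripts/acceptance.py` recomputes the same quantities end to end and
writes them as JSON. Cohort sizes are chosen so the whole suite runs in
well under a minute while keeping Monte-Carlo checks at ±3 SE.

## Known limitations

- Codelists ship as a synthetic placeholder dialect mirroring the
  category structure (delivery procedures, abortion/stillbirth
  diagnoses, sonography tiers with GA windows, preterm codes, drug
  classes); real deployments must supply their vocabulary's codes and
  locally validated GA windows.
- One vocabulary dialect per run; no ICD-9/ICD-10/KCD cross-mapping.
- No mother–infant linkage, no twin/multiple-gestation distinction, and
  no inpatient/outpatient setting logic.
- The confidence-interval method for prevalence is Wilson score by
  default and is a package choice; swap via `ci_method`.
- Episode attribution of markers relies on the plausibility corridor;
  very short interpregnancy intervals can still mis-attribute markers
  in principle (the hierarchy and GA bounds catch most consequences).
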