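# Default algorithm parameters. Every field is optional; omitted fields
# take the same defaults shown here.

# Outcome priority for resolving overlapping episodes (highest first).
# A lower-ranked episode whose outcome date falls within the conflict
# window of a higher-ranked one is treated as miscoded and eliminated.
hierarchy: [stillbirth, delivery, abortion]

# Claims of the same outcome type closer than this many days are one
# episode (single-linkage chaining per person and outcome type).
same_episode_gap_days:
  delivery: 168
  stillbirth: 168
  abortion: 56

# Cross-outcome conflict windows, keyed "a|b" (alphabetical). Any pair
# not listed defaults to the smaller of the two same-episode gaps.
cross_outcome_conflict_days: {}

# Clinically required interval (days) between a pregnancy outcome and
# the start of the next pregnancy; overlapping successor LMPs are pushed
# to previous outcome + retry period.
retry_period_days: 28

# Fixed gestational ages (days) subtracted from the outcome date when no
# GA-informative marker is available: 39, 28 and 10 weeks.
outcome_specific_ga_days:
  delivery: 273
  stillbirth: 196
  abortion: 70

# Fixed GA (35 weeks) implied by a preterm-delivery diagnosis without a
# specified gestational period.
unspecified_preterm_ga_days: 245

# Plausible GA range (days) per final outcome class; the synthetic
# generator also validates its GA distributions against these.
ga_bounds_days:
  full_term: [259, 294]
  preterm: [140, 258]
  stillbirth: [140, 294]
  abortion: [21, 140]

preterm_cutoff_days: 259          # deliveries under 37 weeks are preterm
max_ga_days: 294                  # episodes over 42 weeks are excluded
min_delivery_ga_days: 140         # deliveries under 20 weeks are excluded
stillbirth_reclass_cutoff_days: 140  # stillbirths under 20 weeks -> abortion
max_abortion_ga_days: 140         # kept abortions are capped at 20 weeks

# Completed years at the outcome date, both bounds inclusive.
childbearing_age: [12, 49]

# Pregnancy periods in days since LMP, half-open; a null end means the
# window runs to the outcome date.
trimester_bounds_days:
  - [0, 98]
  - [98, 196]
  - [196, null]

# Preconception quarters in days relative to the LMP, half-open.
preconception_quarters_days:
  - [-360, -270]
  - [-270, -180]
  - [-180, -90]
  - [-90, 0]

# Early-pregnancy reporting window (0-7 weeks).
early_pregnancy_window_days: [0, 49]

# Primary exposure definition: at least this many prescriptions in a
# window (2 == "more than one"); the >=1 sensitivity definition is
# always computed alongside.
exposure_min_prescriptions: 2

# Binomial confidence-interval method for prevalence tables (any method
# accepted by statsmodels proportion_confint).
ci_method: wilson

# If true, sonography tier priority strictly dominates the latest-LMP
# rule; if false, all sonography markers compete on latest LMP directly.
tier_strict: true

# Retry-adjustment trigger: "separated" fires when the LMP precedes the
# previous outcome plus the retry period (output episodes are always
# separated by the retry period); "strict" fires only when the LMP
# precedes the previous outcome date itself.
retry_trigger: separated
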