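# pregepisodes

Identify pregnancy episodes in administrative healthcare claims,
estimate the last menstrual period (LMP), and assess drug exposure
across preconception and pregnancy windows.

Administrative claims record healthcare contacts — dated diagnosis,
procedure and drug codes — not pregnancies. For pharmacoepidemiology
(e.g. use of pregnancy-incompatible immunosuppressants such as
cyclophosphamide, mycophenolate mofetil and methotrexate in systemic
lupus erythematosus), one needs each pregnancy as an *episode*: an LMP
date, an outcome date, and an outcome class. `pregepisodes` implements
a codelist-driven rule pipeline for exactly this:

- **outcome detection** — deliveries from procedure codes; abortions and
  stillbirths from diagnosis codes, restricted to women of childbearing
  age (12–49 years at the outcome);
- **episode clustering** — claims of one outcome type within a
  clinically plausible gap form one episode, anchored at the first
  claim;
- **hierarchy resolution** — overlapping episodes of different types are
  resolved as stillbirth > delivery > abortion; the lower-ranked episode
  is treated as miscoded and eliminated (kept for audit);
- **LMP estimation** — from GA-informative markers (sonography by
  trimester tier, preterm diagnoses, abortion procedures) via
  `LMP = claim date − midpoint(GA window)`, selecting the latest implied
  LMP (smallest gestational age, GA) after tier prioritisation; without
  markers, outcome-specific fixed subtraction of 39 / 28 / 10 weeks for
  delivery / stillbirth / abortion (35 weeks for unspecified preterm);
- **refinement** — a 28-day retry period separates consecutive episodes;
  GA bounds reclassify stillbirths under 20 weeks to abortions, exclude
  deliveries under 20 weeks and any episode over 42 weeks, split
  deliveries at 37 weeks into preterm vs full-term, and subtype
  abortions as induced vs spontaneous;
- **reporting** — outcome prevalence with CIs and GA summaries,
  LMP-method cross-tables, calendar-era strata, and drug-exposure
  trajectories over four preconception quarters and pregnancy periods,
  under both the “>1 prescription” and “≥1 prescription” definitions.

Everything is driven by a codelist CSV and a parameters YAML, so the
pipeline can be re-targeted to any prefix-structured claims dialect. A
placeholder codelist ships for experimentation and testing; a synthetic
cohort generator with known ground truth (`pregepisodes.synthetic`)
backs the entire validation suite — no data download required.

## Worked example

Simulate a default cohort (500 women, seeded) and run the pipeline:

```bash
pregepisodes simulate --out demo/sim
pregepisodes run --claims demo/sim/claims.csv --persons demo/sim/persons.csv \
    --out demo/out --strata-cut 2016-01-01
```

The run prints its stage counts, which always reconcile
(kept + eliminated + excluded = clustered):

```
claims: 2613
persons: 500
events_detected: 790
episodes_clustered: 790
episodes_eliminated: 0
episodes_excluded: 0
episodes_kept: 790
```

`demo/out/episodes.csv` holds one row per episode:

```
person_id,lmp_date,outcome_date,outcome_type,ga_days,lmp_method,status,era_year,reclassified_from,lmp_adjusted_by_retry
W00000,2015-03-22,2015-12-20,full_term,273,outcome_specific,kept,2015,,False
W00001,2005-07-06,2006-04-05,full_term,273,outcome_specific,kept,2005,,False
W00001,2007-09-27,2007-12-15,spontaneous_abortion,79,abortion_procedure,kept,2007,,False
```

The first woman's delivery carried no GA-informative marker, so her LMP
is the fixed 39-week (273-day) subtraction; the second woman's abortion
was dated from an abortion-procedure code, giving an estimated GA of 79
days (~11 weeks). `demo/out/prevalence.csv` starts:

```
outcome,count,proportion,ci_low,ci_high,ga_mean_weeks,...
live_birth,501,0.634,0.600,0.667,38.6,...
full_term,465,0.589,0.554,0.622,38.9,...
preterm,36,0.046,0.033,0.062,34.5,...
stillbirth,23,0.029,0.019,0.043,27.8,...
```

i.e. 63% live births with a mean estimated GA of 38.6 completed weeks.
Note the preterm share is understated relative to the generator's truth
(11% of pregnancies): before the simulated 2016 reimbursement expansion
few preterm/sonography codes are emitted, so markerless preterms are
dated by the 39-week fallback and counted as full-term — the era
behaviour this kind of algorithm exhibits on real claims.
`lmp_methods.csv` tabulates estimation methods by outcome, and
`exposure_trajectory.csv` the per-window drug-exposure percentages.

Library use mirrors the CLI: `generate_cohort`/`emit_claims` produce
records, `run_pipeline_data(claims, persons, codemap, params)` returns
episodes plus a manifest, and `pregepisodes.exposure` holds the
reporting functions.

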