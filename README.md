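# cohortlens

Characterize an index-condition cohort drawn from linked primary-care EHR
data — demography, frailty, comorbidity, coprescription, 3-year follow-up —
and stratify it by trial inclusion/exclusion criteria into eligible and
ineligible populations, with statistical disclosure control applied to every
emitted table.

## Who this is for

Clinical guideline developers weigh randomized-trial evidence whose
eligibility criteria often exclude large parts of the real clinical
population (older patients, the multimorbid, the coprescribed). Judging the
applicability of that evidence needs tailored epidemiology of the people who
actually have the condition: how many would the trial have admitted, and how
do the admitted and excluded groups differ? `cohortlens` is a library (plus
a thin CLI) implementing that analysis pipeline end to end, exercised on a
built-in seeded synthetic EHR generator because real linked primary-care
extracts are access-controlled and not distributable.

## The model and rules at its core

* **Cohort semantics.** At a fixed index date *t₀* (default 2015-11-30),
  the cohort for condition *c* is every patient, with ≥ 2 years of prior
  registration, having a record of *c* on or before *t₀*. Condition
  presence keeps only the **first occurrence**: per (patient, condition),
  min{date of a qualifying code ≤ t₀} across primary-care and hospital
  dialects. Prescriptions are flags over the prior year (t₀ − 365 d, t₀];
  admissions and deaths are truncated at t₀ + 3 years and censored at death.
* **Hierarchies.** Conditions: body system ▸ condition group ▸ individual
  condition; drugs (BNF-style): chapter ▸ class ▸ individual drug. A patient
  with *k* ≥ 2 items under one category counts **once** in that category,
  and the index condition never qualifies for its own comorbidity tables.
* **Scores.** eFI = deficits present / 36, banded Fit ≤ 0.12 < Mild ≤ 0.24
  < Moderate ≤ 0.36 < Severe; Charlson = Σ weights over present conditions.
  Both are precomputed per patient when the store is built.
* **Eligibility.** A patient is eligible iff every inclusion constraint
  (age interval, gender subset, ethnicity subset) holds **and** no exclusion
  (individual conditions, individual drugs, extra demographic rules)
  matches; the cohort is partitioned exactly into the two arms.
* **Disclosure control.** Every count is rounded to the nearest 10 (halves
  away from zero); every percentage is the integer round of 100·raw/raw —
  computed from **unrounded** counts, so a raw cell of 4/50 prints as
  `0 (8)`. Rounding perturbs any count by at most 5 and leaves percentages
  unbiased.

## Worked example

```python
from cohortlens import (GeneratorConfig, build_store, default_catalog,
                        demography_table, disclose, generate, index_cohort)

catalog = default_catalog()
bundle = generate(GeneratorConfig.example(n_patients=5_000, seed=42), *catalog)
store = build_store(bundle, *catalog, index_date="2015-11-30")
cohort = index_cohort(store, "gout")
print(disclose(demography_table(store, cohort, "gout")).cells)
```

prints (abridged; full script in `examples/02_population_analysis.py`):

```
                                             All        Men      Women
All              All                   230 (100)   110 (45)   130 (55)
Age (years)      65-74                   40 (17)    20 (23)    20 (12)
                 75-84                   70 (28)    40 (34)    30 (23)
                 85 and older            40 (17)    10 (12)    30 (20)
IMD quintile     Q1 (least deprived)     60 (24)    30 (24)    30 (24)
                 Q5 (most deprived)      30 (14)    10 (12)    20 (16)
Time since diag. 1 or greater           200 (84)    90 (87)   110 (82)
                 Less than 1             40 (16)    10 (13)    20 (18)
```

The raw cohort is 234 of 5,000 patients; every displayed count is a multiple
of 10 and each percentage is computed from the raw counts (column
percentages within each stratum family; the `All` row is row-oriented). The
age gradient reflects the generator's configured odds multiplier of 1.8 per
decade for gout.

The other example scripts cover the synthetic generator
(`01_synthetic_population.py`), trial eligible/ineligible stratification
(`03_trial_eligibility.py`), the disclosure rules in isolation
(`04_disclosure_rules.py`), and standalone HTML report assembly
(`05_report.py`).

## Command line

```sh
cohortlens generate --out raw/ --n-patients 5000 --seed 42
cohortlens build    --raw raw/ --out store/
cohortlens analyze  --store store/ --condition gout --out tables/
cohortlens trial    --store store/ --condition gout \
    --criteria src/cohortlens/data/gout_trial_criteria.yaml --out trial/
cohortlens report   --store store/ --condition gout --out report.html
```

## Layout

- `src/cohortlens/` — the library: `synthetic` (generator), `catalog`
  (hierarchies + code lists), `store` (optimized per-patient structure),
  `scores` (eFI/Charlson), `analysis` (demography/burden/follow-up tables),
  `eligibility` (trial criteria), `disclosure`, `report`, `cli`.
- `src/cohortlens/data/` — exemplar catalog, synthetic code lists, eFI
  deficit map, Charlson weights, example trial criteria.
- `docs/methods.md` — the methods note: model assumptions, parameter
  defaults, design choices, limitations.
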