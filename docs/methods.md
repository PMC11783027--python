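# Methods

## The analysis model

`cohortlens` implements a fixed-index-date cohort design over five linked
record streams (patients, dated clinical condition codes from primary-care
and hospital sources, dated prescriptions, hospital admissions, deaths).
All analysis is performed against an optimized per-patient store rather
than the raw event streams:

* **First-occurrence reduction.** For presence/absence analyses only the
  earliest qualifying record matters, so the store keeps one row per
  (patient, condition): the minimum date among that condition's codes, in
  either coding dialect, on or before the index date. Events dated after
  the index date are counted in the build log but never ascertain anything;
  adding such an event is provably a no-op (tested as a monotonicity
  property).
* **Prior-year prescriptions.** A (patient, drug) flag exists iff at least
  one prescription falls in the half-open window (index − 365 days, index].
  The day-count convention (365 days rather than one calendar year) is a
  package choice; the two differ only across a leap boundary.
* **Registration rule.** Patients whose registration started after
  index − 2 calendar years are dropped at build time and counted in the
  build log.
* **Follow-up.** Admissions and deaths are truncated at index + 3 calendar
  years; admissions after a patient's death are dropped (and logged).
  Person-years are scaled so a fully followed patient contributes exactly
  3.0 (time in days divided by the horizon length in days, times 3), which
  keeps the "no events → 3.0 person-years" identity exact regardless of
  leap days. Admission rates are reported per 1,000 person-years alongside
  crude 3-year mortality proportions, since "rates" is otherwise ambiguous.
* **Precomputed scores.** eFI and Charlson are computed once per patient at
  build time from the first-occurrence set, so downstream tables never
  rescan events.

### Scores

The eFI follows the cumulative-deficit model: 36 deficits, score =
deficits/36, banded Fit ≤ 0.12 < Mild ≤ 0.24 < Moderate ≤ 0.36 < Severe
(upper bounds inclusive; the bands are exhaustive and mutually exclusive
over [0, 1] and are shipped as configuration so alternative cutoffs can be
supplied). The deficit → condition mapping is a CSV configuration table;
the shipped default maps the exemplar catalog's conditions onto 12 of the
36 standard deficits, so with this catalog the maximum attainable score is
12/36 ≈ 0.33 — severe frailty is reachable only with a richer catalog or a
custom mapping. The Charlson score is the plain sum of a CSV weight table
over present conditions, with no age adjustment; conditions absent from
the table contribute zero, and weights must be non-negative.

### Hierarchies and counting

Conditions form a strict tree (body system ▸ condition group ▸ individual
condition), drugs likewise (chapter ▸ class ▸ drug); loaders reject items
with two parents, so category membership partitions and resolution to any
level is unambiguous. Burden tables count *patients*, not records: a
patient with several qualifying items under a category contributes exactly
one. The index condition is excluded from every comorbidity category's
qualifying set at every level. Top-N selection ranks categories by
whole-cohort count, ties broken by descending count then ascending label
(the ordering must be deterministic; alphabetical tie-break is arbitrary
but stable).

### Eligibility

Inclusion constraints are conjunctive (age interval in whole years with
inclusive bounds, gender subset, ethnicity subset; an unstated dimension
means "any"); exclusions are disjunctive (any named individual condition,
any named individual drug, any extra demographic rule makes the patient
ineligible). Ethnicity "Missing" passes an "any" inclusion but fails an
inclusion subset that names specific groups: a trial that requires specific
ethnicities cannot be shown to admit a patient whose ethnicity is unknown.
Criteria naming group-level conditions or drug classes are rejected —
criteria operate at the individual level only, as does index-condition
selection (both are deliberate scope limits of the emulated design).

### Disclosure control

Two rules, applied to every emitted table: counts round to the nearest 10,
halves away from zero; percentages are integers computed from the **raw**
numerator and denominator, then rounded half away from zero in exact
integer arithmetic. Computing percentages from raw counts is the
consequential interpretation: it produces the `0 (8)` pattern (raw 4 of a
50-patient stratum) and keeps percentage estimates unbiased, at the cost of
visible inconsistency between a disclosed count and its percentage in small
cells. Whether a half rounds up or to even is not observable in integer
tables at this rounding grain except at exact ties; half-away-from-zero is
asserted and used consistently. Every table carries per-cell raw
denominators chosen at construction, which is how the differing percentage
orientations (column-within-family for demography; row-against-stratum for
burden; the mixed orientation of the eligibility summary) are represented
without special-casing the disclosure step. A zero denominator discloses
as an absent percentage, never as 0. No cell suppression or controlled
(additive) rounding is attempted; disclosed families need not sum to 100%.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any real extract's schema or coding idiosyncrasies. Per patient it draws:

* age band from configured weights over the eight analysis bands, then an
  integer age uniform within the band (bands sample 16–24 and 85–100 at
  the edges; 16 rather than 0 so that an "age ≥ 18" inclusion criterion
  has both passing and failing patients, 100 as a pragmatic cap);
* gender (configured proportion of men, default 0.49), ethnicity over the
  five analysis groups (default roughly a UK primary-care mix: 68% White,
  25% missing), deprivation quintile (default uniform);
* registration start uniformly 2–20 years before index;
* condition presence from a logistic model: baseline prevalence is the
  probability for a 50-year-old in quintile 3, odds multiplied by
  `age_odds_per_decade` per decade above 50 and
  `deprivation_odds_per_quintile` per quintile above Q3. Defaults are
  illustrative values a UK primary-care epidemiologist would recognise
  (e.g. gout 2.5% baseline with a steep age gradient of 1.8/decade and a
  slight inverse deprivation gradient of 0.92/quintile; hypertension 14%
  baseline, 2.2/decade, 1.05/quintile), not calibrated to any published
  table;
* for present conditions, an onset date uniform in [registration, index],
  so the configured prevalence is exactly the ascertainable marginal; a
  separate 5% duplicate-record stream (later records for the same
  condition) exercises first-occurrence reduction, a 3% post-index-record
  stream exercises the ascertainment window, and a 10% stale-prescription
  stream (dated 1–2 years before index) exercises the prior-year window;
* prescriptions with a configured probability, optionally conditional on
  carrying a named condition (e.g. allopurinol at 0.45 given gout), dated
  within the prior year;
* death from a constant annual hazard (default 0.03, exponential waiting
  time, recorded only within the 3-year window) and admissions from a
  Poisson process (default 0.3/patient-year) over the exposure censored at
  death.

A single seeded NumPy generator drives every draw in a fixed order, so
(config, seed) determines the bundle byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic disease co-occurrence (conditions are
drawn independently given age and deprivation), gender-specific prevalence,
age-dependent mortality, coding noise and miscoding, transfer-out or
deregistration, and any real extract's table schema. The closed-form
marginal used in tests (enumeration of age-within-band × quintile cells)
is exact for this mechanism, which is what makes the binomial-interval
recovery check sharp.

## Problem sizes

Tests run the generator at 600 patients for fixture cohorts, 20 equivalence
bundles of 120–400 patients for the store-vs-full-scan oracle, and 20,000
patients for the prevalence-recovery check; the acceptance script uses
20,000. These sizes give the recovery check a binomial 99% interval tight
enough to detect calibration errors of a few tenths of a percentage point
while keeping the whole suite fast.

## Numerical and degenerate-input choices

* Age is completed years on the index date.
* "Time since diagnosis < 1 year" means first occurrence strictly after
  index − 1 calendar year; exactly one year before index is prevalent.
* Patients with no deprivation quintile are excluded from the IMD stratum
  family only.
* An empty cohort yields an all-zero table with absent percentages; empty
  follow-up yields zero person-years and absent rates.
* Malformed dates and codes matching no code list are dropped per record
  and tallied in the build log rather than aborting the build.

## Known limitations

Index-condition selection and trial criteria operate at the individual
condition level only; cross-tabulation is fixed to the demographic strata;
follow-up statistics are limited to admission and death summaries (no
outcome modelling); no terminology mapping between coding systems is
attempted (codes are opaque strings); the exemplar catalog is small, and
the shipped eFI/Charlson mappings cover only its conditions.
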