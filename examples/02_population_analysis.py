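"""Characterize a gout cohort: demography, burden, follow-up.

Builds the optimized store (first-occurrence conditions, prior-year drug
flags, precomputed eFI/Charlson, truncated follow-up), selects everyone
with gout recorded on or before the index date, and prints the disclosed
demography table plus the top-5 comorbidity body systems.
"""

from cohortlens import (GeneratorConfig, build_store, burden_table,
                        default_catalog, demography_table, disclose,
                        followup_summary, generate, index_cohort)

catalog = default_catalog()
bundle = generate(GeneratorConfig.example(n_patients=5_000, seed=42), *catalog)
store = build_store(bundle, *catalog, index_date="2015-11-30")
cohort = index_cohort(store, "gout")
print(f"gout cohort: {len(cohort)} of {len(store.patients)} patients\n")

demo = disclose(demography_table(store, cohort, "gout"))
print(demo.cells.to_string(), "\n")
print(demo.footnote(), "\n")

top = disclose(burden_table(store, cohort, "comorbidity", "top", 5, "gout"))
print("top-5 comorbidity body systems (whole cohort, n (%)):")
print(top.cells.loc[("All", "All")].to_string(), "\n")

fu = followup_summary(store, cohort)
print("3-year follow-up (disclosed):", fu.disclosed())
print("Each burden percentage is the share of the stratum with at least one "
      "qualifying condition; gout itself never counts toward its own "
      "comorbidity aggregates.")
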