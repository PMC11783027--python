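"""Assemble a printable standalone HTML report.

Runs the full trial analysis for gout and writes a single self-contained
HTML file (scratch/gout_trial_report.html) containing the selected
disclosed tables, each with its disclosure footnote.
"""

from pathlib import Path

from cohortlens import (GeneratorConfig, ReportSpec, TrialCriteria, build_store,
                        default_catalog, demography_table, disclose,
                        followup_summary, generate, index_cohort,
                        score_distribution, stratify, write_report)
from cohortlens.eligibility import eligibility_table

catalog = default_catalog()
bundle = generate(GeneratorConfig.example(n_patients=5_000, seed=42), *catalog)
store = build_store(bundle, *catalog, index_date="2015-11-30")
cohort = index_cohort(store, "gout")
criteria = TrialCriteria.gout_example()
split = stratify(store, cohort, criteria)

results = {
    "demography": disclose(demography_table(store, cohort, "gout")),
    "efi": disclose(score_distribution(store, cohort, "efi")),
    "followup": followup_summary(store, cohort),
    "eligibility_summary": disclose(eligibility_table(
        store, cohort, split,
        comorbidity_selection=["hypertension"],
        prescription_selection=["thiazide diuretics"],
        index_condition="gout")),
}
spec = ReportSpec(index_condition="gout", analysis_type="trial",
                  selected_sections=["demography", "efi", "followup",
                                     "eligibility_summary"],
                  criteria=criteria)
out = Path(__file__).resolve().parent.parent / "scratch" / "gout_trial_report.html"
out.parent.mkdir(exist_ok=True)
write_report(results, spec, out)
print(f"report written to {out}")
print("Open it in a browser; printing to PDF is the intended export path.")
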