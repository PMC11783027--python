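"""Printable standalone HTML reports of disclosed outputs.

A report is a single self-contained HTML document (inline CSS, no external
assets) assembling user-selected disclosed tables, each followed by the
disclosure footnote that explains the rounding rules and the percentage
orientation.  Every number in a report has already passed disclosure
control; rendering is deterministic given the same results and spec.
PDF output is left to the browser's print path.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .analysis import FollowUpSummary
from .disclosure import DisclosedTable
from .eligibility import TrialCriteria
from .errors import ReportError

SECTIONS = ("demography", "time_since_diagnosis", "efi", "charlson",
            "top_comorbidities", "top_prescriptions", "selected_comorbidities",
            "selected_prescriptions", "followup", "eligibility_summary")

_SECTION_TITLES = {
    "demography": "Demography",
    "time_since_diagnosis": "Time since diagnosis",
    "efi": "Electronic frailty index",
    "charlson": "Charlson comorbidity score",
    "top_comorbidities": "Most frequent comorbidities",
    "top_prescriptions": "Most frequent prescriptions",
    "selected_comorbidities": "User-selected comorbidities",
    "selected_prescriptions": "User-selected prescriptions",
    "followup": "Hospitalization and mortality (3-year follow-up)",
    "eligibility_summary": "Trial eligible vs ineligible populations",
}

_CSS = """
body { font-family: Georgia, serif; margin: 2em auto; max-width: 60em; }
h1 { border-bottom: 2px solid #444; padding-bottom: 0.2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: right; }
th.stratum, td.stratum { text-align: left; }
caption { caption-side: top; font-weight: bold; text-align: left; }
p.footnote { font-size: 0.85em; color: #333; }
footer { margin-top: 2em; font-size: 0.8em; color: #666; }
"""


class ReportSpec(BaseModel):
    """What to assemble into a report."""
    model_config = ConfigDict(extra="forbid")

    index_condition: str
    analysis_type: Literal["population", "trial"]
    selected_sections: list[str] = Field(min_length=1)
    criteria: TrialCriteria | None = None
    title: str | None = None
    footer: str = "Generated by cohortlens; all outputs are disclosure controlled."

    @model_validator(mode="after")
    def _check(self):
        unknown = sorted(set(self.selected_sections) - set(SECTIONS))
        if unknown:
            raise ValueError(f"unknown report sections {unknown}; "
                             f"expected subset of {SECTIONS}")
        if self.analysis_type == "trial" and self.criteria is None:
            raise ValueError("trial analysis requires criteria")
        if self.analysis_type == "population" and self.criteria is not None:
            raise ValueError("criteria are only valid for trial analysis")
        return self


def _render_table(table: DisclosedTable) -> str:
    cols = list(table.cells.columns)
    out = ["<table>", f"<caption>{html.escape(table.name)}</caption>",
           "<tr><th class='stratum'>Criteria (feature)</th>"
           + "".join(f"<th>{html.escape(c)}, n (%)</th>" for c in cols) + "</tr>"]
    last_family = None
    for fam, stratum in table.cells.index:
        if fam != last_family and fam != "All":
            out.append(f"<tr><td class='stratum' colspan='{len(cols) + 1}'>"
                       f"<b>{html.escape(fam)}</b></td></tr>")
        last_family = fam
        cells = "".join(
            f"<td>{html.escape(str(table.cells.loc[(fam, stratum), c]))}</td>"
            for c in cols)
        out.append(f"<tr><td class='stratum'>{html.escape(stratum)}</td>{cells}</tr>")
    out.append("</table>")
    out.append(f"<p class='footnote'>{html.escape(table.footnote())}</p>")
    return "\n".join(out)


def _render_followup(summary: FollowUpSummary) -> str:
    d = summary.disclosed()
    rows = [
        ("Patients", f"{d['n']:,}", "count"),
        ("Patients with ≥1 admission", f"{d['n_admitted']:,}", "count"),
        ("Total admissions", f"{d['total_admissions']:,}", "count"),
        ("Person-years at risk", f"{d['person_years']:,}", "count"),
        ("Admission rate per 1,000 person-years",
         "—" if d["admission_rate_per_1000py"] is None
         else f"{d['admission_rate_per_1000py']:,}", "rate"),
        ("Deaths within 3 years", f"{d['n_died']:,}", "count"),
        ("Crude 3-year mortality (%)",
         "—" if d["mortality_percent"] is None
         else f"{d['mortality_percent']}", "rate"),
    ]
    body = "".join(
        f"<tr><td class='stratum'>{html.escape(k)}</td>"
        f"<td class='{kind}'>{v}</td></tr>" for k, v, kind in rows)
    note = ("Counts and person-years are rounded to the nearest 10; rates are "
            "reported as discrete numbers.")
    return (f"<table><caption>3-year follow-up</caption>{body}</table>"
            f"<p class='footnote'>{note}</p>")


def render_report(results: Mapping[str, DisclosedTable | FollowUpSummary],
                  spec: ReportSpec) -> str:
    """Render the selected sections into one self-contained HTML document."""
    missing = [s for s in spec.selected_sections if s not in results]
    if missing:
        raise ReportError(f"no result supplied for selected sections: {missing}")
    title = spec.title or (
        f"{'Clinical trial population' if spec.analysis_type == 'trial' else 'Index condition population'}"
        f" analysis — {spec.index_condition}")
    parts = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
             f"<title>{html.escape(title)}</title>",
             f"<style>{_CSS}</style></head><body>",
             f"<h1>{html.escape(title)}</h1>"]
    if spec.analysis_type == "trial" and spec.criteria is not None:
        crit = spec.criteria
        inc = []
        if crit.inclusion.age is not None:
            inc.append(f"age {crit.inclusion.age.min or 'any'}–"
                       f"{crit.inclusion.age.max or 'any'} years")
        inc.append("gender: " + (", ".join(sorted(crit.inclusion.gender))
                                 if crit.inclusion.gender else "any"))
        inc.append("ethnicity: " + (", ".join(sorted(crit.inclusion.ethnicity))
                                    if crit.inclusion.ethnicity else "any"))
        exc = []
        if crit.exclusion.conditions:
            exc.append("comorbidities: " + ", ".join(sorted(crit.exclusion.conditions)))
        if crit.exclusion.drugs:
            exc.append("drugs: " + ", ".join(sorted(crit.exclusion.drugs)))
        parts.append(f"<p><b>Trial:</b> {html.escape(crit.name)}<br>"
                     f"<b>Inclusion:</b> {html.escape('; '.join(inc))}<br>"
                     f"<b>Exclusion:</b> {html.escape('; '.join(exc) or 'none')}</p>")
    for section in spec.selected_sections:
        parts.append(f"<h2>{html.escape(_SECTION_TITLES[section])}</h2>")
        result = results[section]
        if isinstance(result, FollowUpSummary):
            parts.append(_render_followup(result))
        elif isinstance(result, DisclosedTable):
            parts.append(_render_table(result))
        else:
            raise ReportError(f"section {section!r} has unsupported result type "
                              f"{type(result).__name__}")
    parts.append(f"<footer>{html.escape(spec.footer)}</footer>")
    parts.append("</body></html>")
    return "\n".join(parts)


def write_report(results: Mapping[str, DisclosedTable | FollowUpSummary],
                 spec: ReportSpec, path: str | Path) -> None:
    Path(path).write_text(render_report(results, spec), encoding="utf-8")
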