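"""Trial inclusion/exclusion criteria and eligible/ineligible stratification.

Criteria are declarative: inclusion constraints on age (whole years,
inclusive bounds), gender and ethnicity, and exclusion constraints on
individual conditions, individual drugs, and optionally age/gender/
ethnicity.  A patient is eligible iff every stated inclusion constraint is
satisfied AND no exclusion constraint matches.  Conditions are tested
against first occurrence on or before the index date; drugs against the
prior-year prescription flags.

Only individual-level condition and drug names are accepted — criteria at
condition-group or body-system level (and drug-class or chapter level) are
rejected, matching the tool's limitation that trial criteria support
comorbidities only at the lower level of the hierarchical groupings.

Ethnicity "Missing" passes an unconstrained ("any") inclusion but fails
any inclusion subset that names specific groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import ConditionHierarchy, DrugHierarchy
from .errors import LevelError, UnknownItemError
from .store import CohortStore
from .strata import GENDERS


class AgeInterval(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min: int | None = Field(default=None, ge=0)
    max: int | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"age interval min {self.min} exceeds max {self.max}")
        return self

    def contains(self, age: int) -> bool:
        return (self.min is None or age >= self.min) and \
               (self.max is None or age <= self.max)


def _parse_subset(value, name: str, allowed: tuple[str, ...]) -> frozenset[str] | None:
    """None or the string "any" mean unconstrained."""
    if value is None or (isinstance(value, str) and value.lower() == "any"):
        return None
    items = frozenset(str(v).lower() if name == "gender" else str(v) for v in value)
    unknown = items - set(allowed)
    if unknown:
        raise ValueError(f"unknown {name} values {sorted(unknown)}; "
                         f"expected subset of {allowed}")
    return items


class InclusionBlock(BaseModel):
    """Unstated dimensions mean "any"."""
    model_config = ConfigDict(extra="forbid")
    age: AgeInterval | None = None
    gender: frozenset[str] | str | None = None
    ethnicity: frozenset[str] | str | None = None

    @model_validator(mode="after")
    def _subsets(self):
        from .strata import ETHNICITY_GROUPS
        object.__setattr__(self, "gender", _parse_subset(self.gender, "gender", GENDERS))
        object.__setattr__(self, "ethnicity",
                           _parse_subset(self.ethnicity, "ethnicity", ETHNICITY_GROUPS))
        return self


class ExclusionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    conditions: frozenset[str] = frozenset()
    drugs: frozenset[str] = frozenset()
    age: list[AgeInterval] = Field(default_factory=list)
    gender: frozenset[str] | str | None = None
    ethnicity: frozenset[str] | str | None = None

    @model_validator(mode="after")
    def _subsets(self):
        from .strata import ETHNICITY_GROUPS
        object.__setattr__(self, "gender", _parse_subset(self.gender, "gender", GENDERS))
        object.__setattr__(self, "ethnicity",
                           _parse_subset(self.ethnicity, "ethnicity", ETHNICITY_GROUPS))
        return self


class TrialCriteria(BaseModel):
    """Declarative inclusion/exclusion criteria for a (notional) trial."""
    model_config = ConfigDict(extra="forbid")
    name: str = "unnamed trial"
    inclusion: InclusionBlock = Field(default_factory=InclusionBlock)
    exclusion: ExclusionBlock = Field(default_factory=ExclusionBlock)

    def validate_against(self, condition_hierarchy: ConditionHierarchy,
                         drug_hierarchy: DrugHierarchy) -> None:
        """Check that every named condition/drug resolves at the individual
        level; group-level names are a hard error, mirroring the tool's
        limitation that criteria support comorbidities only at the lower
        level in the hierarchical groupings of conditions."""
        for name in sorted(self.exclusion.conditions):
            level = condition_hierarchy.level_of(name)
            if level is None:
                raise UnknownItemError(f"unknown condition in criteria: {name!r}")
            if level != "individual":
                raise LevelError(
                    f"criteria support comorbidities only at the individual "
                    f"(lower) level of the hierarchical groupings; {name!r} "
                    f"is a {'condition group' if level == 'group' else 'body system'}")
        for name in sorted(self.exclusion.drugs):
            level = drug_hierarchy.level_of(name)
            if level is None:
                raise UnknownItemError(f"unknown drug in criteria: {name!r}")
            if level != "individual":
                raise LevelError(
                    f"criteria support prescriptions only for individual "
                    f"drugs; {name!r} is a "
                    f"{'drug class' if level == 'group' else 'drug chapter'}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialCriteria":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    @classmethod
    def gout_example(cls) -> "TrialCriteria":
        """The shipped example: adults of any gender/ethnicity, excluding
        selected renal/hepatic/alcohol comorbidities and seven drugs."""
        from importlib import resources
        path = resources.files("cohortlens.data") / "gout_trial_criteria.yaml"
        return cls.model_validate(yaml.safe_load(path.read_text()))


@dataclass(frozen=True)
class PatientView:
    """The per-patient facts eligibility is decided on."""
    age: int
    gender: str
    ethnicity: str
    conditions: frozenset[str]
    drugs: frozenset[str]


@dataclass(frozen=True)
class EligibilitySplit:
    eligible: frozenset[str]
    ineligible: frozenset[str]

    @property
    def cohort(self) -> frozenset[str]:
        return self.eligible | self.ineligible


def classify(view: PatientView,
             criteria: TrialCriteria) -> Literal["eligible", "ineligible"]:
    """Eligible iff every inclusion constraint holds and no exclusion
    constraint matches.  Empty criteria classify everyone as eligible."""
    inc = criteria.inclusion
    if inc.age is not None and not inc.age.contains(view.age):
        return "ineligible"
    if inc.gender is not None and view.gender not in inc.gender:
        return "ineligible"
    if inc.ethnicity is not None and view.ethnicity not in inc.ethnicity:
        return "ineligible"
    exc = criteria.exclusion
    if exc.conditions & view.conditions:
        return "ineligible"
    if exc.drugs & view.drugs:
        return "ineligible"
    if any(iv.contains(view.age) for iv in exc.age):
        return "ineligible"
    if exc.gender is not None and view.gender in exc.gender:
        return "ineligible"
    if exc.ethnicity is not None and view.ethnicity in exc.ethnicity:
        return "ineligible"
    return "eligible"


def patient_views(store: CohortStore, cohort: Iterable[str]) -> dict[str, PatientView]:
    cohort = set(cohort)
    cond_sets = store.condition_sets()
    drug_sets = store.drug_sets()
    views = {}
    sub = store.patients[store.patients["patient_id"].isin(cohort)]
    for row in sub.itertuples():
        views[row.patient_id] = PatientView(
            age=int(row.age_at_index), gender=row.gender, ethnicity=row.ethnicity,
            conditions=frozenset(cond_sets[row.patient_id]),
            drugs=frozenset(drug_sets[row.patient_id]))
    missing = cohort - set(views)
    if missing:
        raise UnknownItemError(f"cohort contains unknown patients: "
                               f"{sorted(missing)[:5]}")
    return views


def stratify(store: CohortStore, cohort: Iterable[str],
             criteria: TrialCriteria) -> EligibilitySplit:
    """Partition *cohort* into eligible and ineligible arms."""
    criteria.validate_against(store.condition_hierarchy, store.drug_hierarchy)
    views = patient_views(store, cohort)
    eligible = frozenset(p for p, v in views.items()
                         if classify(v, criteria) == "eligible")
    return EligibilitySplit(eligible=eligible,
                            ineligible=frozenset(views) - eligible)


def eligibility_table(store: CohortStore, cohort: Iterable[str],
                      split: EligibilitySplit,
                      comorbidity_selection: Iterable[str] = (),
                      comorbidity_level: str = "group",
                      prescription_selection: Iterable[str] = (),
                      prescription_level: str = "class",
                      index_condition: str | None = None):
    """Summary table comparing the whole cohort with each arm.

    Rows: All, age bands, gender, eFI categories, then user-selected
    comorbidity and prescription categories; columns All / Eligible /
    Ineligible.  Percentages are column percentages except in the age and
    gender families, where the Eligible/Ineligible cells are row
    percentages against the All column.
    """
    from .analysis import AGE_FAMILY, GENDER_FAMILY, _category_pairs, _cohort_frame
    from .scores import EFI_CATEGORIES
    from .strata import AGE_BAND_LABELS
    from .tables import RawTable
    import pandas as pd

    cohort = set(cohort)
    if split.cohort != cohort:
        raise ValueError("split does not partition the supplied cohort")
    frame = _cohort_frame(store, cohort)
    arm_of = frame["patient_id"].map(
        lambda p: "Eligible" if p in split.eligible else "Ineligible")
    columns = ["All", "Eligible", "Ineligible"]
    col_mask = {"All": pd.Series(True, index=frame.index),
                "Eligible": arm_of == "Eligible",
                "Ineligible": arm_of == "Ineligible"}
    col_total = {c: int(col_mask[c].sum()) for c in columns}

    rows: list[tuple[str, str, pd.Series]] = [
        ("All", "All", pd.Series(True, index=frame.index))]
    for band in AGE_BAND_LABELS:
        rows.append((AGE_FAMILY, band, frame["age_band"] == band))
    for g in ("Men", "Women"):
        rows.append((GENDER_FAMILY, g, frame["gender_label"] == g))
    for cat in EFI_CATEGORIES:
        rows.append(("eFI", cat, frame["efi_category"] == cat))

    carrier_rows: list[tuple[str, str, set[str]]] = []
    if comorbidity_selection:
        if index_condition is None:
            raise ValueError("index_condition is required for comorbidity rows")
        pairs = _category_pairs(store, cohort, "comorbidity", comorbidity_level,
                                index_condition)
        known = store.condition_hierarchy.labels_at(comorbidity_level)
        unknown = sorted(set(comorbidity_selection) - known)
        if unknown:
            raise UnknownItemError(f"unknown comorbidity categories: {unknown}")
        for c in comorbidity_selection:
            carrier_rows.append((f"Comorbidities ({comorbidity_level}) — user selected",
                                 c, set(pairs.loc[pairs["category"] == c, "patient_id"])))
    if prescription_selection:
        pairs = _category_pairs(store, cohort, "prescription", prescription_level,
                                index_condition or "")
        known = store.drug_hierarchy.labels_at(prescription_level)
        unknown = sorted(set(prescription_selection) - known)
        if unknown:
            raise UnknownItemError(f"unknown prescription categories: {unknown}")
        for c in prescription_selection:
            carrier_rows.append((f"Prescriptions ({prescription_level}) — user selected",
                                 c, set(pairs.loc[pairs["category"] == c, "patient_id"])))

    all_rows = [(f, s) for f, s, _ in rows] + [(f, s) for f, s, _ in carrier_rows]
    index = pd.MultiIndex.from_tuples(all_rows, names=["family", "stratum"])
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    denoms = pd.DataFrame(0, index=index, columns=columns, dtype=int)

    for fam, stratum, mask in rows:
        row_all = int(mask.sum())
        for col in columns:
            counts.loc[(fam, stratum), col] = int((mask & col_mask[col]).sum())
            if fam == "All":
                denoms.loc[(fam, stratum), col] = 0 if col == "All" else col_total["All"]
            elif fam in (AGE_FAMILY, GENDER_FAMILY):
                denoms.loc[(fam, stratum), col] = \
                    col_total["All"] if col == "All" else row_all
            else:  # eFI: column percentages
                denoms.loc[(fam, stratum), col] = col_total[col]
    pid = frame["patient_id"]
    for fam, stratum, carrier in carrier_rows:
        for col in columns:
            ids = set(pid[col_mask[col]])
            counts.loc[(fam, stratum), col] = len(ids & carrier)
            denoms.loc[(fam, stratum), col] = col_total[col]

    orientation = {
        "All": "row percentages of the whole cohort",
        AGE_FAMILY: "All column-wise; Eligible/Ineligible row-wise against the All column",
        GENDER_FAMILY: "All column-wise; Eligible/Ineligible row-wise against the All column",
        "eFI": "column percentages",
    }
    for fam, _, _ in carrier_rows:
        orientation[fam] = "column percentages"
    return RawTable(name="Trial eligible vs ineligible", counts=counts,
                    denominators=denoms, percent_orientation=orientation)
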