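"""Index-condition population analysis.

Produces the raw-count tables that, once disclosure-controlled, mirror the
tool's output tabs: a demography table (age, gender, ethnicity, IMD, time
since diagnosis), comorbidity and prescription burden tables at any
hierarchy level (ranked top-N or user-selected), score distributions (eFI
bands, Charlson bands), and 3-year follow-up summaries of hospital
admission and death.

Counting rules:

* Burden cells count patients, not records: a patient with several
  conditions under one category contributes exactly 1 to that category.
* The index condition is excluded from every comorbidity category's
  qualifying set, so e.g. the body system containing the index condition
  counts only patients with some *other* condition in that system.
* "Time since diagnosis" splits the cohort at one calendar year before the
  index date: first occurrence strictly within that year is "recently
  incident" (< 1 year), otherwise prevalent.
* Patients with no recorded deprivation quintile are omitted from the IMD
  stratum family only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LevelError, UnknownItemError
from .scores import EFI_CATEGORIES
from .store import CohortStore, FOLLOWUP_YEARS
from .strata import AGE_BAND_LABELS, ETHNICITY_GROUPS, GENDER_LABELS, IMD_LABELS, \
    IMD_QUINTILES, TIME_SINCE_DIAGNOSIS_LABELS, age_band_of
from .tables import RawTable

AGE_FAMILY = "Age (years)"
GENDER_FAMILY = "Gender"
ETHNICITY_FAMILY = "Ethnicity"
IMD_FAMILY = "IMD quintile"
TSD_FAMILY = "Time since diagnosis (years)"

CHARLSON_BANDS = ("0", "1", "2", "3-4", "5 or more")

_COMORBIDITY_LEVELS = {"individual", "group", "top", "condition",
                       "condition group", "body system", "body_system"}
_PRESCRIPTION_LEVELS = {"individual", "group", "top", "drug", "class",
                        "drug class", "chapter", "drug chapter"}


def _cohort_frame(store: CohortStore, cohort: Iterable[str]) -> pd.DataFrame:
    cohort = set(cohort)
    unknown = cohort - store.patient_ids
    if unknown:
        raise UnknownItemError(f"cohort contains unknown patients: "
                               f"{sorted(unknown)[:5]}")
    df = store.patients[store.patients["patient_id"].isin(cohort)].copy()
    df["age_band"] = age_band_of(df["age_at_index"]) if len(df) else \
        pd.Series(dtype=str)
    df["gender_label"] = df["gender"].map(GENDER_LABELS)
    df["imd_label"] = df["imd_quintile"].map(IMD_LABELS)
    return df


def _tsd_labels(store: CohortStore, frame: pd.DataFrame, condition: str) -> pd.Series:
    """Prevalent (>= 1 year) vs recently incident (< 1 year) per patient."""
    fo = store.first_occurrence_dates(condition)
    boundary = store.index_date - pd.DateOffset(years=1)
    dates = frame["patient_id"].map(fo)
    return pd.Series(np.where(dates > boundary, TIME_SINCE_DIAGNOSIS_LABELS[1],
                              TIME_SINCE_DIAGNOSIS_LABELS[0]),
                     index=frame.index).where(dates.notna())


def _strata_rows(frame: pd.DataFrame, tsd: pd.Series | None) -> list[tuple[str, str, pd.Series]]:
    """(family, stratum, membership mask) for every fixed demographic stratum."""
    rows: list[tuple[str, str, pd.Series]] = [("All", "All", pd.Series(True, index=frame.index))]
    for band in AGE_BAND_LABELS:
        rows.append((AGE_FAMILY, band, frame["age_band"] == band))
    for g in ("Men", "Women"):
        rows.append((GENDER_FAMILY, g, frame["gender_label"] == g))
    for e in ETHNICITY_GROUPS:
        rows.append((ETHNICITY_FAMILY, e, frame["ethnicity"] == e))
    for q in IMD_QUINTILES:
        rows.append((IMD_FAMILY, IMD_LABELS[q], frame["imd_label"] == IMD_LABELS[q]))
    if tsd is not None:
        for lbl in TIME_SINCE_DIAGNOSIS_LABELS:
            rows.append((TSD_FAMILY, lbl, tsd == lbl))
    return rows


def demography_table(store: CohortStore, cohort: Iterable[str],
                     condition: str) -> RawTable:
    """Counts of cohort patients by the fixed strata, split All/Men/Women.

    Percentages are column percentages within each stratum family; the
    "All" row is row-oriented (Men and Women as shares of the cohort).
    """
    frame = _cohort_frame(store, cohort)
    tsd = _tsd_labels(store, frame, condition)
    rows = _strata_rows(frame, tsd)
    columns = ["All", "Men", "Women"]
    col_mask = {"All": pd.Series(True, index=frame.index),
                "Men": frame["gender_label"] == "Men",
                "Women": frame["gender_label"] == "Women"}
    col_total = {c: int(col_mask[c].sum()) for c in columns}
    n_total = col_total["All"]

    index = pd.MultiIndex.from_tuples([(f, s) for f, s, _ in rows],
                                      names=["family", "stratum"])
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    denoms = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for fam, stratum, mask in rows:
        for col in columns:
            counts.loc[(fam, stratum), col] = int((mask & col_mask[col]).sum())
            denoms.loc[(fam, stratum), col] = n_total if fam == "All" else col_total[col]
    orientation = {
        "All": "row percentages of the whole cohort",
        AGE_FAMILY: "column percentages", GENDER_FAMILY: "column percentages",
        ETHNICITY_FAMILY: "column percentages", IMD_FAMILY: "column percentages",
        TSD_FAMILY: "column percentages",
    }
    return RawTable(name=f"Demography — {condition}", counts=counts,
                    denominators=denoms, percent_orientation=orientation)


def _category_pairs(store: CohortStore, cohort: set[str], kind: str,
                    level: str, index_condition: str) -> pd.DataFrame:
    """Unique (patient_id, category) pairs at the requested level."""
    if kind == "comorbidity":
        if level not in _COMORBIDITY_LEVELS:
            raise LevelError(f"invalid comorbidity level {level!r}")
        h = store.condition_hierarchy
        src = store.first_occurrence
        src = src[src["patient_id"].isin(cohort)
                  & (src["condition"] != index_condition)]
        items = src["condition"]
    elif kind == "prescription":
        if level not in _PRESCRIPTION_LEVELS:
            raise LevelError(f"invalid prescription level {level!r}")
        h = store.drug_hierarchy
        src = store.rx_flags
        src = src[src["patient_id"].isin(cohort)]
        items = src["drug"]
    else:
        raise ValueError(f"kind must be 'comorbidity' or 'prescription', got {kind!r}")
    if not len(src):
        return pd.DataFrame(columns=["patient_id", "category"])
    cats = items.map(lambda x: h.resolve(x, level))
    return (pd.DataFrame({"patient_id": src["patient_id"].values,
                          "category": cats.values})
            .drop_duplicates().reset_index(drop=True))


def burden_table(store: CohortStore, cohort: Iterable[str], kind: str,
                 level: str, selection: int | Sequence[str],
                 index_condition: str) -> RawTable:
    """Comorbidity or prescription burden at one hierarchy level.

    *selection* is either an integer N (the N most frequent categories by
    whole-cohort count, ties broken by descending count then ascending
    label) or an explicit list of category names at that level.  Each cell
    counts patients in the stratum with at least one qualifying condition
    or prior-year prescription in the category; percentages are oriented
    against the stratum size.
    """
    cohort = set(cohort)
    frame = _cohort_frame(store, cohort)
    tsd = _tsd_labels(store, frame, index_condition)
    pairs = _category_pairs(store, cohort, kind, level, index_condition)

    if isinstance(selection, int):
        tally = pairs.groupby("category")["patient_id"].nunique()
        order = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        categories = [c for c, _ in order[:selection]]
    else:
        h = store.condition_hierarchy if kind == "comorbidity" else store.drug_hierarchy
        known = h.labels_at(level)
        unknown = sorted(set(selection) - known)
        if unknown:
            raise UnknownItemError(
                f"unknown {kind} categories at level {level!r}: {unknown}")
        categories = list(selection)

    carriers = {c: set(pairs.loc[pairs["category"] == c, "patient_id"])
                for c in categories}
    rows = _strata_rows(frame, tsd)
    index = pd.MultiIndex.from_tuples([(f, s) for f, s, _ in rows],
                                      names=["family", "stratum"])
    counts = pd.DataFrame(0, index=index, columns=categories, dtype=int)
    denoms = pd.DataFrame(0, index=index, columns=categories, dtype=int)
    pid = frame["patient_id"]
    for fam, stratum, mask in rows:
        stratum_ids = set(pid[mask])
        for c in categories:
            counts.loc[(fam, stratum), c] = len(stratum_ids & carriers[c])
            denoms.loc[(fam, stratum), c] = len(stratum_ids)
    orientation = {fam: "row percentages against the stratum size in the "
                        "demography table" for fam in dict.fromkeys(
                            f for f, _, _ in rows)}
    return RawTable(name=f"{kind.title()} burden ({level}) — {index_condition}",
                    counts=counts, denominators=denoms,
                    percent_orientation=orientation)


def score_distribution(store: CohortStore, cohort: Iterable[str],
                       score: str) -> RawTable:
    """Distribution of eFI categories or banded Charlson scores,
    column-oriented by All/Men/Women."""
    frame = _cohort_frame(store, cohort)
    if score == "efi":
        family, labels = "eFI", EFI_CATEGORIES
        values = frame["efi_category"]
    elif score == "charlson":
        family, labels = "Charlson score", CHARLSON_BANDS
        edges = [-0.5, 0.5, 1.5, 2.5, 4.5, np.inf]
        values = pd.cut(frame["charlson_score"], bins=edges,
                        labels=CHARLSON_BANDS).astype(str)
    else:
        raise ValueError(f"score must be 'efi' or 'charlson', got {score!r}")
    columns = ["All", "Men", "Women"]
    col_mask = {"All": pd.Series(True, index=frame.index),
                "Men": frame["gender_label"] == "Men",
                "Women": frame["gender_label"] == "Women"}
    col_total = {c: int(col_mask[c].sum()) for c in columns}
    index = pd.MultiIndex.from_tuples([(family, lbl) for lbl in labels],
                                      names=["family", "stratum"])
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    denoms = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for lbl in labels:
        for col in columns:
            counts.loc[(family, lbl), col] = int(((values == lbl) & col_mask[col]).sum())
            denoms.loc[(family, lbl), col] = col_total[col]
    return RawTable(name=f"{family} distribution", counts=counts,
                    denominators=denoms,
                    percent_orientation={family: "column percentages"})


@dataclass(frozen=True)
class FollowUpSummary:
    """3-year follow-up: admissions and mortality, censored at death.

    Person-years are scaled so that a patient followed to the full 3-year
    horizon contributes exactly 3.0.  Rates are None when their denominator
    is zero.
    """

    n: int
    n_admitted: int
    total_admissions: int
    person_years: float
    admission_rate_per_1000py: float | None
    n_died: int
    mortality_proportion: float | None

    def disclosed(self) -> dict:
        """Counts rounded to the nearest 10; rates as integers."""
        from .disclosure import round_count
        return {
            "n": round_count(self.n),
            "n_admitted": round_count(self.n_admitted),
            "total_admissions": round_count(self.total_admissions),
            "person_years": round_count(int(round(self.person_years))),
            "admission_rate_per_1000py": None if self.admission_rate_per_1000py is None
            else int(round(self.admission_rate_per_1000py)),
            "n_died": round_count(self.n_died),
            "mortality_percent": None if self.mortality_proportion is None
            else int(round(100 * self.mortality_proportion)),
        }


def followup_summary(store: CohortStore, cohort: Iterable[str]) -> FollowUpSummary:
    """Admission and death summary over (index, index + 3 years]."""
    frame = _cohort_frame(store, cohort)
    ids = set(frame["patient_id"])
    horizon = store.index_date + pd.DateOffset(years=FOLLOWUP_YEARS)
    horizon_days = (horizon - store.index_date).days

    deaths = store.deaths[store.deaths["patient_id"].isin(ids)]
    death_of = dict(zip(deaths["patient_id"], deaths["death_date"]))
    t_days = frame["patient_id"].map(
        lambda p: (death_of[p] - store.index_date).days if p in death_of
        else horizon_days)
    person_years = float(FOLLOWUP_YEARS * t_days.sum() / horizon_days) \
        if horizon_days else 0.0

    adm = store.admissions[store.admissions["patient_id"].isin(ids)]
    total_adm = int(len(adm))
    n_admitted = int(adm["patient_id"].nunique())
    n_died = int(len(death_of))
    n = int(len(frame))
    return FollowUpSummary(
        n=n, n_admitted=n_admitted, total_admissions=total_adm,
        person_years=person_years,
        admission_rate_per_1000py=(1000.0 * total_adm / person_years
                                   if person_years > 0 else None),
        n_died=n_died,
        mortality_proportion=(n_died / n if n else None),
    )
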