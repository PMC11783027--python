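"""Naive full-scan oracle: recomputes every analysis quantity directly from
the raw CSV serialization of a bundle with plain Python dictionaries, never
touching the optimized store.  Deliberately simple and slow."""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

AGE_BANDS = [("Younger than 25", 0, 24), ("25-34", 25, 34), ("35-44", 35, 44),
             ("45-54", 45, 54), ("55-64", 55, 64), ("65-74", 65, 74),
             ("75-84", 75, 84), ("85 and older", 85, 200)]


def shift_years(d: dt.date, years: int) -> dt.date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29
        return d.replace(year=d.year + years, day=28)


def completed_age(index: dt.date, birth: dt.date) -> int:
    return index.year - birth.year - ((index.month, index.day) < (birth.month, birth.day))


def band_of(age: int) -> str:
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValueError(age)


def read_rows(path: Path, name: str) -> list[dict]:
    with open(path / f"{name}.csv", newline="") as fh:
        return list(csv.DictReader(fh))


def load_bundle_dir(path: Path, index: dt.date) -> dict:
    """Parse the raw CSV streams into plain dicts, applying the registration
    rule and deriving completed age."""
    patients = {}
    for row in read_rows(path, "patients"):
        reg = dt.date.fromisoformat(row["registration_start"])
        if reg > shift_years(index, -2):
            continue
        patients[row["patient_id"]] = {
            "age": completed_age(index, dt.date.fromisoformat(row["birth_date"])),
            "gender": row["gender"], "ethnicity": row["ethnicity"],
            "imd": int(row["imd_quintile"]) if row["imd_quintile"] else None,
        }
    return {
        "patients": patients,
        "events": read_rows(path, "clinical_events"),
        "rx": read_rows(path, "prescriptions"),
        "admissions": read_rows(path, "admissions"),
        "deaths": read_rows(path, "deaths"),
    }


def condition_dates(raw: dict, code_map: dict[str, str],
                    index: dt.date) -> dict[tuple[str, str], dt.date]:
    """(patient, condition) -> earliest record date on or before index."""
    out: dict[tuple[str, str], dt.date] = {}
    for row in raw["events"]:
        pid = row["patient_id"]
        if pid not in raw["patients"]:
            continue
        cond = code_map.get(row["code"])
        if cond is None:
            continue
        d = dt.date.fromisoformat(row["date"])
        if d > index:
            continue
        key = (pid, cond)
        if key not in out or d < out[key]:
            out[key] = d
    return out


def rx_flags(raw: dict, known_drugs: set[str], index: dt.date) -> set[tuple[str, str]]:
    out = set()
    lo = index - dt.timedelta(days=365)
    for row in raw["rx"]:
        pid = row["patient_id"]
        if pid not in raw["patients"] or row["drug"] not in known_drugs:
            continue
        d = dt.date.fromisoformat(row["date"])
        if lo < d <= index:
            out.add((pid, row["drug"]))
    return out


def strata_of(raw: dict, pid: str, first: dict, condition: str,
              index: dt.date) -> dict[str, str | None]:
    p = raw["patients"][pid]
    fo = first.get((pid, condition))
    tsd = None
    if fo is not None:
        tsd = "Less than 1" if fo > shift_years(index, -1) else "1 or greater"
    imd_label = {1: "Q1 (least deprived)", 2: "Q2", 3: "Q3", 4: "Q4",
                 5: "Q5 (most deprived)"}.get(p["imd"])
    return {"age": band_of(p["age"]),
            "gender": "Men" if p["gender"] == "men" else "Women",
            "ethnicity": p["ethnicity"], "imd": imd_label, "tsd": tsd}


def demography_counts(raw: dict, cohort: set[str], first: dict, condition: str,
                      index: dt.date) -> dict[tuple[str, str, str], int]:
    """(family, stratum, column) -> count, matching the demography table."""
    counts: dict[tuple[str, str, str], int] = {}

    def bump(fam, stratum, col):
        counts[(fam, stratum, col)] = counts.get((fam, stratum, col), 0) + 1

    for pid in cohort:
        s = strata_of(raw, pid, first, condition, index)
        cols = ["All", s["gender"]]
        for col in cols:
            bump("All", "All", col)
            bump("Age (years)", s["age"], col)
            bump("Gender", s["gender"], col)
            bump("Ethnicity", s["ethnicity"], col)
            if s["imd"] is not None:
                bump("IMD quintile", s["imd"], col)
            if s["tsd"] is not None:
                bump("Time since diagnosis (years)", s["tsd"], col)
    return counts


def burden_counts(raw: dict, cohort: set[str], first: dict, flags: set,
                  kind: str, level_map: dict[str, str], condition: str,
                  index: dt.date) -> dict[tuple[str, str, str], int]:
    """(family, stratum, category) -> patient count with >=1 item mapping to
    the category; level_map maps individual item -> category label."""
    per_patient: dict[str, set[str]] = {pid: set() for pid in cohort}
    if kind == "comorbidity":
        for (pid, cond) in first:
            if pid in per_patient and cond != condition and cond in level_map:
                per_patient[pid].add(level_map[cond])
    else:
        for (pid, drug) in flags:
            if pid in per_patient and drug in level_map:
                per_patient[pid].add(level_map[drug])
    counts: dict[tuple[str, str, str], int] = {}
    for pid in cohort:
        s = strata_of(raw, pid, first, condition, index)
        rows = [("All", "All"), ("Age (years)", s["age"]),
                ("Gender", s["gender"]), ("Ethnicity", s["ethnicity"])]
        if s["imd"] is not None:
            rows.append(("IMD quintile", s["imd"]))
        if s["tsd"] is not None:
            rows.append(("Time since diagnosis (years)", s["tsd"]))
        for cat in per_patient[pid]:
            for fam, stratum in rows:
                counts[(fam, stratum, cat)] = counts.get((fam, stratum, cat), 0) + 1
    return counts


def followup(raw: dict, cohort: set[str], index: dt.date) -> dict:
    horizon = shift_years(index, 3)
    horizon_days = (horizon - index).days
    death_of = {}
    for row in raw["deaths"]:
        if row["patient_id"] in cohort:
            d = dt.date.fromisoformat(row["death_date"])
            if index < d <= horizon:
                if row["patient_id"] not in death_of or d < death_of[row["patient_id"]]:
                    death_of[row["patient_id"]] = d
    total_adm = 0
    admitted = set()
    for row in raw["admissions"]:
        pid = row["patient_id"]
        if pid not in cohort:
            continue
        d = dt.date.fromisoformat(row["admission_date"])
        if not (index < d <= horizon):
            continue
        if pid in death_of and d > death_of[pid]:
            continue
        total_adm += 1
        admitted.add(pid)
    t_days = sum((death_of[p] - index).days if p in death_of else horizon_days
                 for p in cohort)
    py = 3.0 * t_days / horizon_days if horizon_days else 0.0
    return {"n": len(cohort), "n_admitted": len(admitted),
            "total_admissions": total_adm, "person_years": py,
            "n_died": len(death_of)}


def eligible_set(raw: dict, cohort: set[str], first: dict, flags: set,
                 criteria: dict) -> set[str]:
    """criteria: dict with optional keys age_min, age_max, genders,
    ethnicities, excl_conditions, excl_drugs, excl_age (list of (lo, hi))."""
    out = set()
    conds_of: dict[str, set[str]] = {p: set() for p in cohort}
    for (pid, cond) in first:
        if pid in conds_of:
            conds_of[pid].add(cond)
    drugs_of: dict[str, set[str]] = {p: set() for p in cohort}
    for (pid, drug) in flags:
        if pid in drugs_of:
            drugs_of[pid].add(drug)
    for pid in cohort:
        p = raw["patients"][pid]
        age = p["age"]
        ok = True
        if criteria.get("age_min") is not None and age < criteria["age_min"]:
            ok = False
        if criteria.get("age_max") is not None and age > criteria["age_max"]:
            ok = False
        if criteria.get("genders") is not None and p["gender"] not in criteria["genders"]:
            ok = False
        if criteria.get("ethnicities") is not None and \
                p["ethnicity"] not in criteria["ethnicities"]:
            ok = False
        if conds_of[pid] & set(criteria.get("excl_conditions", ())):
            ok = False
        if drugs_of[pid] & set(criteria.get("excl_drugs", ())):
            ok = False
        for lo, hi in criteria.get("excl_age", ()):
            if (lo is None or age >= lo) and (hi is None or age <= hi):
                ok = False
        if ok:
            out.add(pid)
    return out
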