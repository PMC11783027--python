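"""Raw EHR bundles and the optimized per-patient cohort store.

A :class:`RawEHRBundle` carries the five linked record streams the tool
consumes: patients, dated clinical condition codes (primary-care and
hospital dialects), dated drug prescriptions, hospital admissions, and
death records.

:func:`build_store` reduces the raw streams to the minimum needed for
analysis at a fixed index date:

* per (patient, condition), only the earliest qualifying record date on or
  before the index date (first occurrence);
* per (patient, drug), a flag for at least one prescription in the year
  before the index date;
* follow-up admissions and deaths truncated at three years after index;
* precomputed per-patient eFI score/category and Charlson score.

Patients with less than two years of registration before the index date are
dropped and counted in the build log, as are records whose codes match no
code list or whose dates cannot be parsed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catalog import ConditionHierarchy, DrugHierarchy, load_condition_hierarchy, \
    load_drug_hierarchy
from .errors import CatalogError, LevelError, UnknownItemError
from .scores import DEFAULT_EFI_CUTOFFS, DeficitMap, categorise_efi, load_charlson_weights, \
    load_deficit_map, N_DEFICITS
from .strata import age_at

PATIENT_COLUMNS = ("patient_id", "birth_date", "gender", "ethnicity",
                   "imd_quintile", "registration_start")
EVENT_COLUMNS = ("patient_id", "code", "date", "source")
RX_COLUMNS = ("patient_id", "drug", "date")
ADMISSION_COLUMNS = ("patient_id", "admission_date")
DEATH_COLUMNS = ("patient_id", "death_date")

_STREAMS = {
    "patients": PATIENT_COLUMNS,
    "clinical_events": EVENT_COLUMNS,
    "prescriptions": RX_COLUMNS,
    "admissions": ADMISSION_COLUMNS,
    "deaths": DEATH_COLUMNS,
}

PRESCRIPTION_WINDOW_DAYS = 365  # half-open (index - 365 d, index]
FOLLOWUP_YEARS = 3
REGISTRATION_YEARS = 2


def _empty_frame(columns: tuple[str, ...]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class RawEHRBundle:
    """The five linked patient-level record streams."""

    patients: pd.DataFrame
    clinical_events: pd.DataFrame
    prescriptions: pd.DataFrame
    admissions: pd.DataFrame
    deaths: pd.DataFrame

    def validate(self) -> None:
        for name, cols in _STREAMS.items():
            df = getattr(self, name)
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} stream lacks columns {sorted(missing)}")
        ids = self.patients["patient_id"]
        if ids.duplicated().any():
            raise ValueError(
                f"duplicate patient ids: {sorted(ids[ids.duplicated()].unique())}")
        known = set(ids)
        for name in ("clinical_events", "prescriptions", "admissions", "deaths"):
            df = getattr(self, name)
            orphans = set(df["patient_id"]) - known
            if orphans:
                raise ValueError(f"{name} references unknown patients: "
                                 f"{sorted(orphans)[:5]}")

    @classmethod
    def empty(cls) -> "RawEHRBundle":
        return cls(**{name: _empty_frame(cols) for name, cols in _STREAMS.items()})

    def to_csv_dir(self, path: str | Path) -> None:
        """Write the five streams as CSV files with documented headers."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, cols in _STREAMS.items():
            df = getattr(self, name).copy()
            for c in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[c]):
                    df[c] = df[c].dt.strftime("%Y-%m-%d")
            df.to_csv(path / f"{name}.csv", index=False, columns=list(cols))

    @classmethod
    def from_csv_dir(cls, path: str | Path) -> "RawEHRBundle":
        path = Path(path)
        frames = {}
        for name, cols in _STREAMS.items():
            df = pd.read_csv(path / f"{name}.csv", dtype=str, keep_default_na=False)
            frames[name] = df.reindex(columns=list(cols))
        return cls(**frames)


@dataclass
class CohortStore:
    """Optimized per-patient analysis structure for one index date.

    ``patients`` carries demography plus ``age_at_index``, ``efi_score``,
    ``efi_category`` and ``charlson_score``; ``first_occurrence`` holds one
    row per (patient, condition) with the earliest qualifying date;
    ``rx_flags`` one row per (patient, drug) prescribed in the prior year;
    ``admissions``/``deaths`` are truncated to the 3-year follow-up window.
    """

    index_date: pd.Timestamp
    patients: pd.DataFrame
    first_occurrence: pd.DataFrame
    rx_flags: pd.DataFrame
    admissions: pd.DataFrame
    deaths: pd.DataFrame
    condition_hierarchy: ConditionHierarchy
    drug_hierarchy: DrugHierarchy
    build_log: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> frozenset[str]:
        return frozenset(self.patients["patient_id"])

    def condition_sets(self) -> dict[str, set[str]]:
        """patient -> set of conditions first-occurring on/before index."""
        out: dict[str, set[str]] = {p: set() for p in self.patients["patient_id"]}
        for pid, cond in zip(self.first_occurrence["patient_id"],
                             self.first_occurrence["condition"]):
            out[pid].add(cond)
        return out

    def drug_sets(self) -> dict[str, set[str]]:
        """patient -> set of drugs prescribed in the prior-year window."""
        out: dict[str, set[str]] = {p: set() for p in self.patients["patient_id"]}
        for pid, drug in zip(self.rx_flags["patient_id"], self.rx_flags["drug"]):
            out[pid].add(drug)
        return out

    def first_occurrence_dates(self, condition: str) -> pd.Series:
        sub = self.first_occurrence[self.first_occurrence["condition"] == condition]
        return pd.Series(sub["date"].values, index=sub["patient_id"].values)


def _coerce_dates(df: pd.DataFrame, col: str, log: dict, key: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
    n_bad = int(bad.sum())
    if n_bad:
        log[key] = log.get(key, 0) + n_bad
    df = df.loc[~bad].copy()
    df[col] = parsed.loc[~bad]
    return df


def build_store(raw: RawEHRBundle,
                condition_hierarchy: ConditionHierarchy,
                drug_hierarchy: DrugHierarchy,
                index_date: str | pd.Timestamp,
                deficit_map: DeficitMap | None = None,
                charlson_weights: Mapping[str, int] | None = None,
                efi_cutoffs=DEFAULT_EFI_CUTOFFS) -> CohortStore:
    """Reduce a raw bundle to the optimized store for *index_date*."""
    raw.validate()
    index_ts = pd.Timestamp(index_date)
    deficit_map = deficit_map or load_deficit_map()
    charlson_weights = dict(charlson_weights or load_charlson_weights())
    log: dict = {}

    patients = raw.patients.copy()
    patients = _coerce_dates(patients, "birth_date", log, "patients_malformed_date")
    patients = _coerce_dates(patients, "registration_start", log, "patients_malformed_date")
    cutoff = index_ts - pd.DateOffset(years=REGISTRATION_YEARS)
    ok = patients["registration_start"] <= cutoff
    log["patients_dropped_registration"] = int((~ok).sum())
    patients = patients.loc[ok].reset_index(drop=True)
    patients["imd_quintile"] = pd.to_numeric(
        patients["imd_quintile"], errors="coerce").astype("Int64")
    patients["age_at_index"] = (
        age_at(index_ts, patients["birth_date"]) if len(patients) else
        pd.Series(dtype=int))
    known = set(patients["patient_id"])

    # --- first-occurrence reduction -------------------------------------
    events = raw.clinical_events.copy()
    events = events[events["patient_id"].isin(known)]
    events = _coerce_dates(events, "date", log, "events_malformed_date")
    code_map = condition_hierarchy.code_to_condition()
    events["condition"] = events["code"].map(code_map)
    log["events_unmapped_code"] = int(events["condition"].isna().sum())
    events = events.dropna(subset=["condition"])
    log["events_after_index"] = int((events["date"] > index_ts).sum())
    events = events[events["date"] <= index_ts]
    if len(events):
        first = (events.groupby(["patient_id", "condition"], as_index=False)["date"]
                 .min().sort_values(["patient_id", "condition"]).reset_index(drop=True))
    else:
        first = pd.DataFrame(columns=["patient_id", "condition", "date"])

    # --- prior-year prescription flags ----------------------------------
    rx = raw.prescriptions.copy()
    rx = rx[rx["patient_id"].isin(known)]
    rx = _coerce_dates(rx, "date", log, "rx_malformed_date")
    rx["drug"] = rx["drug"].where(rx["drug"].isin(drug_hierarchy.individuals))
    log["rx_unmapped_drug"] = int(rx["drug"].isna().sum())
    rx = rx.dropna(subset=["drug"])
    lo = index_ts - pd.Timedelta(days=PRESCRIPTION_WINDOW_DAYS)
    in_window = (rx["date"] > lo) & (rx["date"] <= index_ts)
    log["rx_outside_window"] = int((~in_window).sum())
    rx = rx[in_window]
    rx_flags = (rx[["patient_id", "drug"]].drop_duplicates()
                .sort_values(["patient_id", "drug"]).reset_index(drop=True))

    # --- 3-year follow-up, truncated at death ---------------------------
    horizon = index_ts + pd.DateOffset(years=FOLLOWUP_YEARS)
    deaths = raw.deaths.copy()
    deaths = deaths[deaths["patient_id"].isin(known)]
    deaths = _coerce_dates(deaths, "death_date", log, "deaths_malformed_date")
    log["deaths_outside_window"] = int(
        ((deaths["death_date"] <= index_ts) | (deaths["death_date"] > horizon)).sum())
    deaths = deaths[(deaths["death_date"] > index_ts) & (deaths["death_date"] <= horizon)]
    deaths = (deaths.groupby("patient_id", as_index=False)["death_date"].min()
              .sort_values("patient_id").reset_index(drop=True))
    death_of = dict(zip(deaths["patient_id"], deaths["death_date"]))

    adm = raw.admissions.copy()
    adm = adm[adm["patient_id"].isin(known)]
    adm = _coerce_dates(adm, "admission_date", log, "admissions_malformed_date")
    in_fu = (adm["admission_date"] > index_ts) & (adm["admission_date"] <= horizon)
    log["admissions_outside_window"] = int((~in_fu).sum())
    adm = adm[in_fu]
    if len(adm):
        limit = adm["patient_id"].map(death_of)
        after_death = limit.notna() & (adm["admission_date"] > limit)
        log["admissions_after_death"] = int(after_death.sum())
        adm = adm[~after_death]
    adm = adm.sort_values(["patient_id", "admission_date"]).reset_index(drop=True)

    # --- precomputed scores ---------------------------------------------
    efi_count = pd.Series(0, index=patients["patient_id"], dtype=int)
    charlson = pd.Series(0, index=patients["patient_id"], dtype=int)
    if len(first):
        pairs = first[["patient_id", "condition"]].copy()
        pairs["deficits"] = pairs["condition"].map(
            lambda c: sorted(deficit_map.condition_to_deficits.get(c, ())))
        exploded = pairs.explode("deficits").dropna(subset=["deficits"])
        counts = exploded.drop_duplicates(["patient_id", "deficits"]) \
            .groupby("patient_id").size()
        efi_count.loc[counts.index] = counts
        w = pairs["condition"].map(charlson_weights).fillna(0).astype(int)
        csum = w.groupby(pairs["patient_id"]).sum()
        charlson.loc[csum.index] = csum
    patients["efi_score"] = (efi_count / N_DEFICITS).values
    patients["efi_category"] = [categorise_efi(s, efi_cutoffs)
                                for s in patients["efi_score"]]
    patients["charlson_score"] = charlson.values

    return CohortStore(
        index_date=index_ts,
        patients=patients,
        first_occurrence=first,
        rx_flags=rx_flags,
        admissions=adm[["patient_id", "admission_date"]],
        deaths=deaths,
        condition_hierarchy=condition_hierarchy,
        drug_hierarchy=drug_hierarchy,
        build_log=log,
    )


def index_cohort(store: CohortStore, condition: str) -> frozenset[str]:
    """Patients with a first-occurrence record for *condition*.

    Index selection is individual-level only: naming a condition group or
    body system raises :class:`LevelError`.
    """
    h = store.condition_hierarchy
    level = h.level_of(condition)
    if level is None:
        raise UnknownItemError(f"unknown condition {condition!r}")
    if level != "individual":
        raise LevelError(
            f"index selection is individual-level only; {condition!r} is a "
            f"{'condition group' if level == 'group' else 'body system'}")
    if condition not in h.index_eligible:
        raise CatalogError(f"condition {condition!r} has no code list and is "
                           "not selectable as an index condition")
    sub = store.first_occurrence
    return frozenset(sub.loc[sub["condition"] == condition, "patient_id"])


# ---------------------------------------------------------------------------
# persistence

def _catalog_checksum(cond: ConditionHierarchy, drug: DrugHierarchy) -> str:
    h = hashlib.sha256()
    for item in sorted(cond.entries):
        h.update(f"{item}|{cond.entries[item]}".encode())
        for src in sorted(cond.code_lists.get(item, {})):
            h.update(f"{src}:{sorted(cond.code_lists[item][src])}".encode())
    for item in sorted(drug.entries):
        h.update(f"{item}|{drug.entries[item]}".encode())
    return h.hexdigest()


def save_store(store: CohortStore, path: str | Path) -> None:
    """Persist the store as parquet files plus a JSON manifest; the catalog
    travels with the store so it can be reloaded without rebuilding."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in ("patients", "first_occurrence", "rx_flags", "admissions", "deaths"):
        getattr(store, name).to_parquet(path / f"{name}.parquet", index=False)
    cond_rows = [{"condition": c, "group": g, "body_system": b}
                 for c, (g, b) in sorted(store.condition_hierarchy.entries.items())]
    pd.DataFrame(cond_rows).to_csv(path / "conditions.csv", index=False)
    code_rows = [{"condition": c, "source": s, "code": code}
                 for c, by_src in sorted(store.condition_hierarchy.code_lists.items())
                 for s, codes in sorted(by_src.items()) for code in sorted(codes)]
    pd.DataFrame(code_rows, columns=["condition", "source", "code"]) \
        .to_csv(path / "code_lists.csv", index=False)
    drug_rows = [{"drug": d, "class": cl, "chapter": ch}
                 for d, (cl, ch) in sorted(store.drug_hierarchy.entries.items())]
    pd.DataFrame(drug_rows).to_csv(path / "drugs.csv", index=False)
    manifest = {
        "index_date": store.index_date.strftime("%Y-%m-%d"),
        "catalog_checksum": _catalog_checksum(store.condition_hierarchy,
                                              store.drug_hierarchy),
        "build_log": store.build_log,
        "n_patients": int(len(store.patients)),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_store(path: str | Path) -> CohortStore:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cond = load_condition_hierarchy(path / "conditions.csv",
                                    path / "code_lists.csv"
                                    if (path / "code_lists.csv").stat().st_size > 30
                                    else None)
    drug = load_drug_hierarchy(path / "drugs.csv")
    frames = {name: pd.read_parquet(path / f"{name}.parquet")
              for name in ("patients", "first_occurrence", "rx_flags",
                           "admissions", "deaths")}
    store = CohortStore(index_date=pd.Timestamp(manifest["index_date"]),
                        condition_hierarchy=cond, drug_hierarchy=drug,
                        build_log=manifest["build_log"], **frames)
    if _catalog_checksum(cond, drug) != manifest["catalog_checksum"]:
        raise ValueError("catalog files do not match the manifest checksum")
    return store
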