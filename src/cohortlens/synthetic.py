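"""Seeded generator of synthetic linked-EHR bundles.

The generator emulates the statistical structure the downstream analysis
assumes: a fixed index date, at least two years of prior registration,
condition records dated on or before the index date, prescriptions
concentrated in the prior year, and three years of admission/death
follow-up, over a population with age/gender/ethnicity/deprivation
structure.

Condition presence is drawn per patient from a logistic model: a baseline
prevalence (the probability for a 50-year-old in deprivation quintile 3)
whose odds are multiplied by ``age_odds_per_decade`` for every decade of
age above 50 and by ``deprivation_odds_per_quintile`` for every quintile
above Q3.  Presence means a record dated on or before the index date, so
the configured prevalence is exactly the quantity the ascertainment step
recovers.  Separate, smaller record streams exercise the filters the
analysis applies: duplicate later records for the same condition
(first-occurrence reduction), records dated after the index date
(ascertainment window), and stale prescriptions older than a year
(prior-year window).

Identical (config, seed) pairs produce byte-identical bundles.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .catalog import ConditionHierarchy, DrugHierarchy, default_catalog
from .errors import ConfigurationError
from .store import RawEHRBundle
from .strata import AGE_BANDS, AGE_BAND_LABELS, ETHNICITY_GROUPS, IMD_QUINTILES

_WEIGHT_TOL = 1e-9


def _check_weights(name: str, weights: Mapping, expected_keys) -> None:
    if set(weights) != set(expected_keys):
        raise ValueError(
            f"{name} must have keys {sorted(map(str, expected_keys))}, "
            f"got {sorted(map(str, weights))}")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{name} has negative weights")
    total = float(sum(weights.values()))
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"{name} weights sum to {total!r}, not 1")


class ConditionParams(BaseModel):
    """Logistic prevalence model for one condition."""
    model_config = ConfigDict(extra="forbid")

    prevalence: float = Field(ge=0.0, le=1.0)
    age_odds_per_decade: float = Field(default=1.0, ge=0.0)
    deprivation_odds_per_quintile: float = Field(default=1.0, ge=0.0)


class PrescriptionParams(BaseModel):
    """Probability of a prior-year prescription, optionally conditional on
    carrying a named condition."""
    model_config = ConfigDict(extra="forbid")

    probability: float = Field(ge=0.0, le=1.0)
    condition: str | None = None


class GeneratorConfig(BaseModel):
    """Full description of a synthetic study population.

    Categorical weights must sum to 1 (within 1e-9); all probabilities lie
    in [0, 1].  ``index_date`` defaults to 2015-11-30, the index date of
    the exemplar study design this generator emulates.
    """
    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=0)
    index_date: dt.date = dt.date(2015, 11, 30)
    age_distribution: dict[str, float]
    gender_split: float = Field(default=0.49, ge=0.0, le=1.0,
                                description="proportion of men")
    ethnicity_weights: dict[str, float]
    imd_weights: dict[int, float]
    condition_params: dict[str, ConditionParams] = Field(default_factory=dict)
    prescription_params: dict[str, PrescriptionParams] = Field(default_factory=dict)
    admission_rate: float = Field(default=0.3, ge=0.0,
                                  description="expected admissions per patient-year")
    mortality_rate: float = Field(default=0.03, ge=0.0, le=1.0,
                                  description="annual death hazard")
    duplicate_record_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    post_index_record_fraction: float = Field(default=0.03, ge=0.0, le=1.0)
    stale_prescription_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("age_distribution")
    @classmethod
    def _age_weights(cls, v):
        _check_weights("age_distribution", v, AGE_BAND_LABELS)
        return v

    @field_validator("ethnicity_weights")
    @classmethod
    def _eth_weights(cls, v):
        _check_weights("ethnicity_weights", v, ETHNICITY_GROUPS)
        return v

    @field_validator("imd_weights")
    @classmethod
    def _imd_weights(cls, v):
        _check_weights("imd_weights", v, IMD_QUINTILES)
        return v

    @classmethod
    def example(cls, n_patients: int = 20_000, seed: int = 0) -> "GeneratorConfig":
        """Defaults emulating a UK primary-care population in which gout is
        the exemplar index condition: a mostly White adult population, gout
        prevalence near 3% rising steeply with age and slightly falling
        with deprivation, and cardiometabolic comorbidity that rises with
        both age and deprivation."""
        return cls(
            n_patients=n_patients,
            seed=seed,
            age_distribution={"Younger than 25": 0.10, "25-34": 0.15,
                              "35-44": 0.16, "45-54": 0.17, "55-64": 0.15,
                              "65-74": 0.13, "75-84": 0.10, "85 and older": 0.04},
            gender_split=0.49,
            ethnicity_weights={"Black": 0.02, "Chinese or Mixed or Other": 0.02,
                               "South Asian": 0.03, "White": 0.68, "Missing": 0.25},
            imd_weights={1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2},
            condition_params={
                "gout": ConditionParams(prevalence=0.025, age_odds_per_decade=1.8,
                                        deprivation_odds_per_quintile=0.92),
                "hypertension": ConditionParams(prevalence=0.14, age_odds_per_decade=2.2,
                                                deprivation_odds_per_quintile=1.05),
                "myocardial infarction": ConditionParams(
                    prevalence=0.025, age_odds_per_decade=1.9,
                    deprivation_odds_per_quintile=1.12),
                "angina": ConditionParams(prevalence=0.03, age_odds_per_decade=1.9,
                                          deprivation_odds_per_quintile=1.1),
                "atrial fibrillation": ConditionParams(
                    prevalence=0.02, age_odds_per_decade=2.0),
                "heart failure": ConditionParams(prevalence=0.015,
                                                 age_odds_per_decade=2.1),
                "osteoarthritis": ConditionParams(prevalence=0.10,
                                                  age_odds_per_decade=1.9),
                "rheumatoid arthritis": ConditionParams(prevalence=0.01,
                                                        age_odds_per_decade=1.4),
                "osteoporosis": ConditionParams(prevalence=0.03,
                                                age_odds_per_decade=2.0),
                "peptic ulcer": ConditionParams(prevalence=0.03, age_odds_per_decade=1.4,
                                                deprivation_odds_per_quintile=1.1),
                "gastro-oesophageal reflux": ConditionParams(
                    prevalence=0.08, age_odds_per_decade=1.3),
                "liver failure": ConditionParams(prevalence=0.004,
                                                 deprivation_odds_per_quintile=1.2),
                "chronic obstructive pulmonary disease": ConditionParams(
                    prevalence=0.04, age_odds_per_decade=1.7,
                    deprivation_odds_per_quintile=1.25),
                "asthma": ConditionParams(prevalence=0.09,
                                          deprivation_odds_per_quintile=1.05),
                "chronic kidney disease": ConditionParams(prevalence=0.04,
                                                          age_odds_per_decade=2.2),
                "end-stage renal disease": ConditionParams(prevalence=0.003,
                                                           age_odds_per_decade=1.3),
                "urinary incontinence": ConditionParams(prevalence=0.025,
                                                        age_odds_per_decade=1.6),
                "diabetes": ConditionParams(prevalence=0.06, age_odds_per_decade=1.6,
                                            deprivation_odds_per_quintile=1.15),
                "hypothyroidism": ConditionParams(prevalence=0.04,
                                                  age_odds_per_decade=1.3),
                "depression": ConditionParams(prevalence=0.12,
                                              deprivation_odds_per_quintile=1.15),
                "alcohol misuse": ConditionParams(prevalence=0.03,
                                                  deprivation_odds_per_quintile=1.3),
                "Hodgkin lymphoma": ConditionParams(prevalence=0.001),
                "leukemia": ConditionParams(prevalence=0.002,
                                            age_odds_per_decade=1.3),
                "metastatic solid tumour": ConditionParams(prevalence=0.004,
                                                           age_odds_per_decade=1.5),
            },
            prescription_params={
                "allopurinol": PrescriptionParams(probability=0.45, condition="gout"),
                "colchicine": PrescriptionParams(probability=0.12, condition="gout"),
                "naproxen": PrescriptionParams(probability=0.12),
                "bendroflumethiazide": PrescriptionParams(probability=0.30,
                                                          condition="hypertension"),
                "indapamide": PrescriptionParams(probability=0.06,
                                                 condition="hypertension"),
                "hydrochlorothiazide": PrescriptionParams(probability=0.02,
                                                          condition="hypertension"),
                "cyclopenthiazide": PrescriptionParams(probability=0.01,
                                                       condition="hypertension"),
                "losartan": PrescriptionParams(probability=0.15,
                                               condition="hypertension"),
                "candesartan": PrescriptionParams(probability=0.10,
                                                  condition="hypertension"),
                "aspirin": PrescriptionParams(probability=0.45,
                                              condition="myocardial infarction"),
                "simvastatin": PrescriptionParams(probability=0.15),
                "atorvastatin": PrescriptionParams(probability=0.10),
                "warfarin": PrescriptionParams(probability=0.35,
                                               condition="atrial fibrillation"),
                "apixaban": PrescriptionParams(probability=0.20,
                                               condition="atrial fibrillation"),
                "omeprazole": PrescriptionParams(probability=0.55,
                                                 condition="gastro-oesophageal reflux"),
                "mesalazine": PrescriptionParams(probability=0.01),
                "sulfasalazine": PrescriptionParams(probability=0.25,
                                                    condition="rheumatoid arthritis"),
                "paracetamol": PrescriptionParams(probability=0.25),
                "amitriptyline": PrescriptionParams(probability=0.35,
                                                    condition="depression"),
                "metformin": PrescriptionParams(probability=0.70, condition="diabetes"),
                "levothyroxine": PrescriptionParams(probability=0.85,
                                                    condition="hypothyroidism"),
            },
            admission_rate=0.30,
            mortality_rate=0.03,
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def _condition_probability(params: ConditionParams, ages: np.ndarray,
                           imd: np.ndarray) -> np.ndarray:
    """Per-patient presence probability under the logistic model."""
    p0 = params.prevalence
    if p0 in (0.0, 1.0):
        return np.full(ages.shape, p0)
    logit = np.log(p0 / (1 - p0))
    if params.age_odds_per_decade > 0:
        logit = logit + np.log(params.age_odds_per_decade) * (ages - 50) / 10.0
    else:
        return np.zeros(ages.shape)
    if params.deprivation_odds_per_quintile > 0:
        logit = logit + np.log(params.deprivation_odds_per_quintile) * (imd - 3)
    else:
        return np.zeros(ages.shape)
    return 1.0 / (1.0 + np.exp(-logit))


def expected_prevalence(config: GeneratorConfig, condition: str) -> float:
    """Closed-form marginal prevalence of *condition* under *config*,
    obtained by enumerating the age-within-band x deprivation strata."""
    params = config.condition_params[condition]
    total = 0.0
    for label, lo, hi in AGE_BANDS:
        band_w = config.age_distribution[label]
        ages = np.arange(lo, hi + 1, dtype=float)
        for q in IMD_QUINTILES:
            p = _condition_probability(params, ages, np.full(ages.shape, float(q)))
            total += band_w * config.imd_weights[q] * float(np.mean(p))
    return total


def _validate_against_catalog(config: GeneratorConfig, cond_h: ConditionHierarchy,
                              drug_h: DrugHierarchy) -> None:
    unknown = sorted(set(config.condition_params) - set(cond_h.individuals))
    if unknown:
        raise ConfigurationError(
            f"condition_params refers to conditions absent from the catalog: {unknown}")
    uncoded = sorted(c for c in config.condition_params
                     if not any(cond_h.code_lists.get(c, {}).values()))
    if uncoded:
        raise ConfigurationError(
            f"condition_params refers to conditions without code lists: {uncoded}")
    unknown_drugs = sorted(set(config.prescription_params) - set(drug_h.individuals))
    if unknown_drugs:
        raise ConfigurationError(
            f"prescription_params refers to drugs absent from the catalog: {unknown_drugs}")
    bad_link = sorted(p.condition for p in config.prescription_params.values()
                      if p.condition is not None
                      and p.condition not in config.condition_params)
    if bad_link:
        raise ConfigurationError(
            f"prescription_params conditional on conditions not being generated: {bad_link}")


def generate(config: GeneratorConfig,
             condition_hierarchy: ConditionHierarchy | None = None,
             drug_hierarchy: DrugHierarchy | None = None) -> RawEHRBundle:
    """Generate a synthetic raw bundle; (config, seed) fully determines it."""
    if condition_hierarchy is None or drug_hierarchy is None:
        default_cond, default_drug = default_catalog()
        condition_hierarchy = condition_hierarchy or default_cond
        drug_hierarchy = drug_hierarchy or default_drug
    _validate_against_catalog(config, condition_hierarchy, drug_hierarchy)

    n = config.n_patients
    if n == 0:
        return RawEHRBundle.empty()
    rng = np.random.default_rng(config.seed)
    index_ts = pd.Timestamp(config.index_date)

    # --- demography -----------------------------------------------------
    pids = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    band_idx = rng.choice(len(AGE_BANDS), size=n,
                          p=[config.age_distribution[b] for b in AGE_BAND_LABELS])
    lows = np.array([lo for _, lo, _ in AGE_BANDS])[band_idx]
    highs = np.array([hi for _, _, hi in AGE_BANDS])[band_idx]
    ages = lows + rng.integers(0, highs - lows + 1)
    anchor_off = rng.integers(0, 365, size=n)
    anchor = pd.DatetimeIndex(index_ts - pd.to_timedelta(anchor_off, unit="D"))
    day = np.where((anchor.month == 2) & (anchor.day == 29), 28, anchor.day)
    birth = pd.to_datetime(pd.DataFrame({"year": anchor.year - ages,
                                         "month": anchor.month, "day": day}))
    gender = np.where(rng.random(n) < config.gender_split, "men", "women")
    ethnicity = rng.choice(ETHNICITY_GROUPS, size=n,
                           p=[config.ethnicity_weights[e] for e in ETHNICITY_GROUPS])
    imd = rng.choice(np.array(IMD_QUINTILES), size=n,
                     p=[config.imd_weights[q] for q in IMD_QUINTILES])
    reg_off = rng.integers(732, 7305, size=n)  # 2 to ~20 years before index
    registration = pd.DatetimeIndex(index_ts - pd.to_timedelta(reg_off, unit="D"))

    patients = pd.DataFrame({
        "patient_id": pids, "birth_date": birth, "gender": gender,
        "ethnicity": ethnicity, "imd_quintile": imd.astype(int),
        "registration_start": registration,
    })

    # --- condition records ----------------------------------------------
    ev_pid, ev_code, ev_date, ev_src = [], [], [], []

    def _emit(pid_arr, cond: str, dates, source_draw):
        prim = sorted(condition_hierarchy.codes_for(cond, "primary"))
        hosp = sorted(condition_hierarchy.codes_for(cond, "hospital"))
        use_hosp = source_draw & (len(hosp) > 0)
        pools = np.where(use_hosp, "hospital", "primary")
        for pid, d, src in zip(pid_arr, dates, pools):
            codes = hosp if src == "hospital" else prim
            ev_pid.append(pid)
            ev_code.append(codes[rng.integers(0, len(codes))])
            ev_date.append(d)
            ev_src.append(src)

    carriers: dict[str, np.ndarray] = {}
    ages_f = ages.astype(float)
    imd_f = imd.astype(float)
    for cond in sorted(config.condition_params):
        params = config.condition_params[cond]
        p = _condition_probability(params, ages_f, imd_f)
        has = rng.random(n) < p
        carriers[cond] = has
        idx = np.flatnonzero(has)
        if idx.size == 0:
            continue
        span = (index_ts - registration[idx]).days.to_numpy()
        onset_off = (rng.random(idx.size) * span).astype(int)
        onset = index_ts - pd.to_timedelta(span - onset_off, unit="D")
        src_draw = rng.random(idx.size) < 0.2
        _emit(pids[idx], cond, onset, src_draw)
        # later duplicate records for the same condition, to be reduced away
        dup = rng.random(idx.size) < config.duplicate_record_fraction
        if dup.any():
            j = np.flatnonzero(dup)
            remain = (index_ts - pd.DatetimeIndex(onset[j])).days.to_numpy()
            dup_off = (rng.random(j.size) * (remain + 1)).astype(int)
            dup_dates = pd.DatetimeIndex(onset[j]) + pd.to_timedelta(dup_off, unit="D")
            _emit(pids[idx[j]], cond, dup_dates, rng.random(j.size) < 0.2)

    # records dated after index, which ascertainment must ignore
    post = np.flatnonzero(rng.random(n) < config.post_index_record_fraction)
    if post.size and config.condition_params:
        names = sorted(config.condition_params)
        picks = rng.integers(0, len(names), size=post.size)
        off = rng.integers(1, 1096, size=post.size)
        dates = index_ts + pd.to_timedelta(off, unit="D")
        for k, (i, c) in enumerate(zip(post, picks)):
            _emit(pids[i:i + 1], names[c], dates[k:k + 1],
                  rng.random(1) < 0.2)

    clinical = pd.DataFrame({"patient_id": ev_pid, "code": ev_code,
                             "date": pd.DatetimeIndex(ev_date), "source": ev_src})
    clinical = clinical.sort_values(["patient_id", "date", "code"],
                                    kind="mergesort").reset_index(drop=True)

    # --- prescriptions ---------------------------------------------------
    rx_pid, rx_drug, rx_date = [], [], []
    for drug in sorted(config.prescription_params):
        params = config.prescription_params[drug]
        eligible = carriers[params.condition] if params.condition else \
            np.ones(n, dtype=bool)
        take = eligible & (rng.random(n) < params.probability)
        idx = np.flatnonzero(take)
        if idx.size == 0:
            continue
        off = rng.integers(0, 365, size=idx.size)
        rx_pid.extend(pids[idx])
        rx_drug.extend([drug] * idx.size)
        rx_date.extend(index_ts - pd.to_timedelta(off, unit="D"))
    stale = np.flatnonzero(rng.random(n) < config.stale_prescription_fraction)
    if stale.size and config.prescription_params:
        names = sorted(config.prescription_params)
        picks = rng.integers(0, len(names), size=stale.size)
        off = rng.integers(366, 731, size=stale.size)
        rx_pid.extend(pids[stale])
        rx_drug.extend([names[c] for c in picks])
        rx_date.extend(index_ts - pd.to_timedelta(off, unit="D"))
    prescriptions = pd.DataFrame({"patient_id": rx_pid, "drug": rx_drug,
                                  "date": pd.DatetimeIndex(rx_date)})
    prescriptions = prescriptions.sort_values(["patient_id", "drug", "date"],
                                              kind="mergesort").reset_index(drop=True)

    # --- follow-up: deaths then admissions censored at death -------------
    if config.mortality_rate > 0:
        t_death = rng.exponential(1.0 / config.mortality_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
        rng.exponential(1.0, size=n)  # keep the draw sequence stable
    horizon_days = (index_ts + pd.DateOffset(years=3) - index_ts).days
    death_days = np.where(t_death <= 3.0,
                          np.minimum(np.ceil(t_death * 365.25), horizon_days), np.nan)
    death_days = np.where(death_days < 1, 1, death_days)
    died = ~np.isnan(death_days)
    deaths = pd.DataFrame({
        "patient_id": pids[died],
        "death_date": index_ts + pd.to_timedelta(death_days[died], unit="D"),
    }).sort_values("patient_id").reset_index(drop=True)

    exposure_days = np.where(died, death_days, horizon_days).astype(int)
    lam = config.admission_rate * exposure_days / 365.25
    n_adm = rng.poisson(lam)
    total = int(n_adm.sum())
    adm_pid = np.repeat(pids, n_adm)
    adm_limit = np.repeat(exposure_days, n_adm)
    adm_off = np.ceil(rng.random(total) * adm_limit).astype(int)
    adm_off = np.clip(adm_off, 1, adm_limit)
    admissions = pd.DataFrame({
        "patient_id": adm_pid,
        "admission_date": index_ts + pd.to_timedelta(adm_off, unit="D"),
    }).sort_values(["patient_id", "admission_date"],
                   kind="mergesort").reset_index(drop=True)

    bundle = RawEHRBundle(patients=patients, clinical_events=clinical,
                          prescriptions=prescriptions, admissions=admissions,
                          deaths=deaths)
    bundle.validate()
    return bundle
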