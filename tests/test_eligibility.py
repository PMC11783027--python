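"""Trial criteria classification and cohort stratification."""

import datetime as dt

import numpy as np
import pytest

from cohortlens import (PatientView, TrialCriteria, build_store, classify,
                        index_cohort, stratify)
from cohortlens.eligibility import (AgeInterval, ExclusionBlock, InclusionBlock,
                                    eligibility_table)
from cohortlens.errors import LevelError, UnknownItemError

import naive

INDEX = "2015-11-30"


def view(age=60, gender="men", ethnicity="White", conditions=(), drugs=()):
    return PatientView(age=age, gender=gender, ethnicity=ethnicity,
                       conditions=frozenset(conditions), drugs=frozenset(drugs))


def test_excluded_drug_makes_ineligible():
    crit = TrialCriteria.gout_example()
    assert classify(view(drugs={"bendroflumethiazide"}), crit) == "ineligible"
    assert classify(view(drugs={"allopurinol"}), crit) == "eligible"


def test_inclusion_age_bound():
    crit = TrialCriteria(inclusion=InclusionBlock(age=AgeInterval(min=18)))
    assert classify(view(age=17), crit) == "ineligible"
    assert classify(view(age=18), crit) == "eligible"


def test_empty_criteria_everyone_eligible():
    crit = TrialCriteria()
    assert classify(view(), crit) == "eligible"
    assert classify(view(age=5, gender="women", ethnicity="Missing",
                         conditions={"gout"}, drugs={"aspirin"}), crit) == "eligible"


def test_excluded_condition_makes_ineligible():
    crit = TrialCriteria.gout_example()
    assert classify(view(conditions={"end-stage renal disease"}), crit) == "ineligible"
    assert classify(view(conditions={"chronic kidney disease"}), crit) == "eligible"


def test_missing_ethnicity_passes_any_but_fails_named_subset():
    any_crit = TrialCriteria(inclusion=InclusionBlock(ethnicity="any"))
    named = TrialCriteria(inclusion=InclusionBlock(ethnicity={"White", "Black"}))
    assert classify(view(ethnicity="Missing"), any_crit) == "eligible"
    assert classify(view(ethnicity="Missing"), named) == "ineligible"


def test_group_level_condition_in_criteria_rejected(catalog):
    cond_h, drug_h = catalog
    crit = TrialCriteria(exclusion=ExclusionBlock(
        conditions={"coronary heart disease"}))
    with pytest.raises(LevelError, match="lower"):
        crit.validate_against(cond_h, drug_h)
    crit2 = TrialCriteria(exclusion=ExclusionBlock(drugs={"thiazide diuretics"}))
    with pytest.raises(LevelError, match="individual drugs"):
        crit2.validate_against(cond_h, drug_h)
    crit3 = TrialCriteria(exclusion=ExclusionBlock(conditions={"dragon pox"}))
    with pytest.raises(UnknownItemError):
        crit3.validate_against(cond_h, drug_h)


def test_stratify_is_a_partition(small_store, gout_cohort):
    split = stratify(small_store, gout_cohort, TrialCriteria.gout_example())
    assert split.eligible | split.ineligible == frozenset(gout_cohort)
    assert not (split.eligible & split.ineligible)


def test_noop_exclusion_leaves_split_unchanged(small_store, gout_cohort):
    """Excluding a drug prescribed to nobody in the cohort changes nothing."""
    base = TrialCriteria.gout_example()
    flags = small_store.rx_flags
    in_cohort = set(flags.loc[flags["patient_id"].isin(gout_cohort), "drug"])
    unused = sorted(small_store.drug_hierarchy.individuals - in_cohort)
    assert unused, "fixture cohort unexpectedly uses every catalog drug"
    widened = base.model_copy(update={"exclusion": base.exclusion.model_copy(
        update={"drugs": frozenset(set(base.exclusion.drugs) | {unused[0]})})})
    a = stratify(small_store, gout_cohort, base)
    b = stratify(small_store, gout_cohort, widened)
    assert a.eligible == b.eligible and a.ineligible == b.ineligible


def test_single_exclusion_matches_raw_scan(small_bundle, small_store,
                                           gout_cohort, catalog, tmp_path):
    """'Exclude condition X' yields exactly the X-carriers as ineligible,
    verified by exhaustive per-patient re-evaluation of the raw events."""
    cond_h, drug_h = catalog
    index = dt.date(2015, 11, 30)
    small_bundle.to_csv_dir(tmp_path / "raw")
    raw = naive.load_bundle_dir(tmp_path / "raw", index)
    first = naive.condition_dates(raw, cond_h.code_to_condition(), index)
    flags = naive.rx_flags(raw, set(drug_h.individuals), index)
    crit = TrialCriteria(exclusion=ExclusionBlock(conditions={"hypertension"}))
    split = stratify(small_store, gout_cohort, crit)
    expected = naive.eligible_set(raw, set(gout_cohort), first, flags,
                                  {"excl_conditions": {"hypertension"}})
    assert split.eligible == expected


def test_random_criteria_partition_and_raw_scan(small_bundle, small_store,
                                                gout_cohort, catalog, tmp_path):
    cond_h, drug_h = catalog
    index = dt.date(2015, 11, 30)
    small_bundle.to_csv_dir(tmp_path / "raw")
    raw = naive.load_bundle_dir(tmp_path / "raw", index)
    first = naive.condition_dates(raw, cond_h.code_to_condition(), index)
    flags = naive.rx_flags(raw, set(drug_h.individuals), index)
    rng = np.random.default_rng(5)
    conditions = sorted(cond_h.individuals)
    drugs = sorted(drug_h.individuals)
    for _ in range(25):
        age_min = int(rng.integers(0, 60)) if rng.random() < 0.5 else None
        age_max = int(rng.integers(60, 110)) if rng.random() < 0.5 else None
        genders = frozenset(rng.choice(["men", "women"], size=1)) \
            if rng.random() < 0.3 else None
        excl_c = frozenset(rng.choice(conditions,
                                      size=rng.integers(0, 4), replace=False))
        excl_d = frozenset(rng.choice(drugs, size=rng.integers(0, 4),
                                      replace=False))
        crit = TrialCriteria(
            inclusion=InclusionBlock(age=AgeInterval(min=age_min, max=age_max),
                                     gender=genders),
            exclusion=ExclusionBlock(conditions=excl_c, drugs=excl_d))
        split = stratify(small_store, gout_cohort, crit)
        assert split.eligible | split.ineligible == frozenset(gout_cohort)
        assert not (split.eligible & split.ineligible)
        expected = naive.eligible_set(
            raw, set(gout_cohort), first, flags,
            {"age_min": age_min, "age_max": age_max,
             "genders": genders, "excl_conditions": excl_c, "excl_drugs": excl_d})
        assert split.eligible == expected


def test_adding_constraints_never_grows_eligible(small_store, gout_cohort):
    base = TrialCriteria()
    tighter = TrialCriteria(inclusion=InclusionBlock(age=AgeInterval(min=40)))
    tightest = TrialCriteria(inclusion=InclusionBlock(age=AgeInterval(min=40)),
                             exclusion=ExclusionBlock(conditions={"hypertension"}))
    e0 = stratify(small_store, gout_cohort, base).eligible
    e1 = stratify(small_store, gout_cohort, tighter).eligible
    e2 = stratify(small_store, gout_cohort, tightest).eligible
    assert e2 <= e1 <= e0


def test_eligibility_table_shape_and_sums(small_store, gout_cohort):
    split = stratify(small_store, gout_cohort, TrialCriteria.gout_example())
    t = eligibility_table(small_store, gout_cohort, split,
                          comorbidity_selection=["hypertension",
                                                 "coronary heart disease"],
                          prescription_selection=["statins", "thiazide diuretics"],
                          index_condition="gout")
    assert t.counts.loc[("All", "All"), "Eligible"] == len(split.eligible)
    assert t.counts.loc[("All", "All"), "Ineligible"] == len(split.ineligible)
    age = t.counts.loc["Age (years)"]
    assert (age["Eligible"] + age["Ineligible"]).equals(age["All"])
    efi = t.counts.loc["eFI"]
    assert efi["All"].sum() == len(gout_cohort)
    assert efi["Eligible"].sum() == len(split.eligible)
    # excluded-drug class shows up (nearly) only in the ineligible arm
    thia = t.counts.loc[("Prescriptions (class) — user selected",
                         "thiazide diuretics")]
    assert thia["Eligible"] == 0
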