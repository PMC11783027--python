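"""Population-analysis tables against brute-force recounts."""

import datetime as dt

import pandas as pd
import pytest

from cohortlens import (build_store, burden_table, demography_table,
                        followup_summary, index_cohort, score_distribution)
from cohortlens.errors import LevelError, UnknownItemError

import naive

INDEX = "2015-11-30"


def test_single_patient_bookkeeping(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid="p1", age=70, gender="men",
                                   ethnicity="White", imd=1)],
                    events=[("p1", code_p, "2010-06-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    t = demography_table(store, {"p1"}, "gout")
    nonzero = {(fam, s, c): int(v)
               for (fam, s), row in t.counts.iterrows()
               for c, v in row.items() if v}
    assert nonzero == {
        ("All", "All", "All"): 1, ("All", "All", "Men"): 1,
        ("Age (years)", "65-74", "All"): 1, ("Age (years)", "65-74", "Men"): 1,
        ("Gender", "Men", "All"): 1, ("Gender", "Men", "Men"): 1,
        ("Ethnicity", "White", "All"): 1, ("Ethnicity", "White", "Men"): 1,
        ("IMD quintile", "Q1 (least deprived)", "All"): 1,
        ("IMD quintile", "Q1 (least deprived)", "Men"): 1,
        ("Time since diagnosis (years)", "1 or greater", "All"): 1,
        ("Time since diagnosis (years)", "1 or greater", "Men"): 1,
    }


def test_empty_cohort_is_all_zero(small_store):
    t = demography_table(small_store, set(), "gout")
    assert (t.counts.to_numpy() == 0).all()


def test_partition_invariants(small_store, gout_cohort):
    t = demography_table(small_store, gout_cohort, "gout")
    n = len(gout_cohort)
    for family in ("Age (years)", "Gender", "Time since diagnosis (years)"):
        assert t.counts.loc[family, "All"].sum() == n
    # Men + Women = All for every row
    assert (t.counts["Men"] + t.counts["Women"]).equals(t.counts["All"])


def test_time_since_diagnosis_boundary(make_bundle, catalog, gout_codes):
    """First occurrence strictly within the year before index is 'recently
    incident'; exactly one year before is prevalent."""
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid="p1"), dict(pid="p2")],
                    events=[("p1", code_p, "2014-11-30", "primary"),
                            ("p2", code_p, "2014-12-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    t = demography_table(store, {"p1", "p2"}, "gout")
    tsd = t.counts.loc["Time since diagnosis (years)", "All"]
    assert tsd["1 or greater"] == 1 and tsd["Less than 1"] == 1


def test_demography_matches_naive_full_scan(small_bundle, small_store,
                                            gout_cohort, catalog, tmp_path):
    cond_h, _ = catalog
    small_bundle.to_csv_dir(tmp_path / "raw")
    raw = naive.load_bundle_dir(tmp_path / "raw", dt.date(2015, 11, 30))
    first = naive.condition_dates(raw, cond_h.code_to_condition(),
                                  dt.date(2015, 11, 30))
    expected = naive.demography_counts(raw, set(gout_cohort), first, "gout",
                                       dt.date(2015, 11, 30))
    t = demography_table(small_store, gout_cohort, "gout")
    for (fam, stratum), row in t.counts.iterrows():
        for col, v in row.items():
            assert int(v) == expected.get((fam, stratum, col), 0), (fam, stratum, col)


def test_same_category_counts_once(make_bundle, catalog):
    """A patient with two circulatory conditions contributes one patient to
    the circulatory body system."""
    cond_h, _ = catalog
    chd = sorted(cond_h.codes_for("myocardial infarction", "primary"))[0]
    htn = sorted(cond_h.codes_for("hypertension", "primary"))[0]
    gout = sorted(cond_h.codes_for("gout", "primary"))[0]
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", chd, "2010-01-01", "primary"),
                            ("p1", htn, "2011-01-01", "primary"),
                            ("p1", gout, "2012-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    t = burden_table(store, {"p1"}, "comorbidity", "top",
                     ["disease of the circulatory system"], "gout")
    assert t.counts.loc[("All", "All"), "disease of the circulatory system"] == 1


def test_index_condition_excluded_from_own_burden(make_bundle, catalog, gout_codes):
    """A gout-only patient contributes nothing to musculoskeletal conditions;
    a gout+osteoarthritis patient contributes one."""
    code_p, _ = gout_codes
    cond_h, _ = catalog
    oa = sorted(cond_h.codes_for("osteoarthritis", "primary"))[0]
    b = make_bundle(patients=[dict(pid="p1"), dict(pid="p2")],
                    events=[("p1", code_p, "2010-01-01", "primary"),
                            ("p2", code_p, "2010-01-01", "primary"),
                            ("p2", oa, "2011-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    t = burden_table(store, {"p1", "p2"}, "comorbidity", "top",
                     ["musculoskeletal conditions"], "gout")
    assert t.counts.loc[("All", "All"), "musculoskeletal conditions"] == 1


def test_top_n_ranking_and_tie_break(make_bundle, catalog):
    cond_h, _ = catalog
    dm = sorted(cond_h.codes_for("diabetes", "primary"))[0]
    ast = sorted(cond_h.codes_for("asthma", "primary"))[0]
    dep = sorted(cond_h.codes_for("depression", "primary"))[0]
    gout = sorted(cond_h.codes_for("gout", "primary"))[0]
    events = [("p1", gout, "2010-01-01", "primary"),
              ("p2", gout, "2010-01-01", "primary"),
              ("p3", gout, "2010-01-01", "primary"),
              # diabetes x2; asthma x1 and depression x1 tie at 1
              ("p1", dm, "2011-01-01", "primary"),
              ("p2", dm, "2011-01-01", "primary"),
              ("p1", ast, "2011-01-01", "primary"),
              ("p2", dep, "2011-01-01", "primary")]
    b = make_bundle(patients=[dict(pid=p) for p in ("p1", "p2", "p3")],
                    events=events)
    store = build_store(b, *catalog, index_date=INDEX)
    t = burden_table(store, {"p1", "p2", "p3"}, "comorbidity", "individual",
                     3, "gout")
    # descending count, then ascending label for the 1-1 tie
    assert list(t.counts.columns) == ["diabetes", "asthma", "depression"]


def test_burden_monotone_across_levels(small_store, gout_cohort):
    body = burden_table(small_store, gout_cohort, "comorbidity", "top",
                        ["disease of the circulatory system"], "gout")
    group = burden_table(small_store, gout_cohort, "comorbidity", "group",
                         ["coronary heart disease"], "gout")
    indiv = burden_table(small_store, gout_cohort, "comorbidity", "individual",
                         ["myocardial infarction"], "gout")
    b = body.counts.loc[("All", "All"), "disease of the circulatory system"]
    g = group.counts.loc[("All", "All"), "coronary heart disease"]
    i = indiv.counts.loc[("All", "All"), "myocardial infarction"]
    assert b >= g >= i


def test_burden_cells_bounded_by_stratum_size(small_store, gout_cohort):
    t = burden_table(small_store, gout_cohort, "prescription", "top", 5, "gout")
    assert (t.counts.to_numpy() <= t.denominators.to_numpy()).all()


def test_burden_matches_naive_full_scan(small_bundle, small_store, gout_cohort,
                                        catalog, tmp_path):
    cond_h, drug_h = catalog
    index = dt.date(2015, 11, 30)
    small_bundle.to_csv_dir(tmp_path / "raw")
    raw = naive.load_bundle_dir(tmp_path / "raw", index)
    first = naive.condition_dates(raw, cond_h.code_to_condition(), index)
    flags = naive.rx_flags(raw, set(drug_h.individuals), index)
    level_map = {d: drug_h.resolve(d, "top") for d in drug_h.individuals}
    expected = naive.burden_counts(raw, set(gout_cohort), first, flags,
                                   "prescription", level_map, "gout", index)
    t = burden_table(small_store, gout_cohort, "prescription", "top", 5, "gout")
    # the chosen top-5 categories must agree with a naive tally and sort
    all_counts = {}
    for (fam, stratum, cat), v in expected.items():
        if (fam, stratum) == ("All", "All"):
            all_counts[cat] = v
    naive_top = sorted(all_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    assert list(t.counts.columns) == [c for c, _ in naive_top]
    for (fam, stratum), row in t.counts.iterrows():
        for cat, v in row.items():
            assert int(v) == expected.get((fam, stratum, cat), 0)


def test_unknown_explicit_selection_rejected(small_store, gout_cohort):
    with pytest.raises(UnknownItemError, match="dragon"):
        burden_table(small_store, gout_cohort, "comorbidity", "group",
                     ["hypertension", "dragon pox"], "gout")
    with pytest.raises(LevelError):
        burden_table(small_store, gout_cohort, "comorbidity", "chapter",
                     5, "gout")


def test_followup_no_events(make_bundle, catalog):
    store = build_store(make_bundle(patients=[dict(pid="p1")]), *catalog,
                        index_date=INDEX)
    fu = followup_summary(store, {"p1"})
    assert fu.person_years == pytest.approx(3.0)
    assert fu.total_admissions == 0 and fu.n_died == 0
    assert fu.mortality_proportion == 0.0


def test_followup_death_mid_window(make_bundle, catalog):
    idx = pd.Timestamp(INDEX)
    horizon_days = (idx + pd.DateOffset(years=3) - idx).days
    half = horizon_days // 2
    b = make_bundle(patients=[dict(pid="p1")],
                    admissions=[("p1", idx + pd.Timedelta(days=100))],
                    deaths=[("p1", idx + pd.Timedelta(days=half))])
    store = build_store(b, *catalog, index_date=INDEX)
    fu = followup_summary(store, {"p1"})
    assert fu.person_years == pytest.approx(3.0 * half / horizon_days)
    assert fu.admission_rate_per_1000py == pytest.approx(1000 / fu.person_years)
    assert fu.mortality_proportion == 1.0


def test_followup_empty_cohort(small_store):
    fu = followup_summary(small_store, set())
    assert fu.person_years == 0.0
    assert fu.admission_rate_per_1000py is None
    assert fu.mortality_proportion is None


def test_followup_matches_naive(small_bundle, small_store, gout_cohort, tmp_path):
    index = dt.date(2015, 11, 30)
    small_bundle.to_csv_dir(tmp_path / "raw")
    raw = naive.load_bundle_dir(tmp_path / "raw", index)
    expected = naive.followup(raw, set(gout_cohort), index)
    fu = followup_summary(small_store, gout_cohort)
    assert fu.n == expected["n"]
    assert fu.n_admitted == expected["n_admitted"]
    assert fu.total_admissions == expected["total_admissions"]
    assert fu.n_died == expected["n_died"]
    assert fu.person_years == pytest.approx(expected["person_years"])


def test_score_distribution_sums_to_cohort(small_store, gout_cohort):
    for which in ("efi", "charlson"):
        t = score_distribution(small_store, gout_cohort, which)
        assert t.counts["All"].sum() == len(gout_cohort)
        assert (t.counts["Men"] + t.counts["Women"]).equals(t.counts["All"])


def test_imd_missing_excluded_from_imd_family_only(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid="p1", imd=None), dict(pid="p2", imd=2)],
                    events=[("p1", code_p, "2010-01-01", "primary"),
                            ("p2", code_p, "2010-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    t = demography_table(store, {"p1", "p2"}, "gout")
    assert t.counts.loc["IMD quintile", "All"].sum() == 1
    assert t.counts.loc["Age (years)", "All"].sum() == 2
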