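"""Cohort store build: first-occurrence reduction, windows, cohort selection."""

import pandas as pd
import pytest

from cohortlens import build_store, index_cohort, load_store, save_store
from cohortlens.errors import LevelError, UnknownItemError

INDEX = "2015-11-30"


def test_first_occurrence_is_minimum_event_date(make_bundle, catalog, gout_codes):
    code_p, code_h = gout_codes
    b = make_bundle(
        patients=[dict(pid="p1")],
        events=[("p1", code_p, "2012-01-01", "primary"),
                ("p1", code_p, "2010-05-01", "primary"),
                ("p1", code_h, "2014-03-03", "hospital")],
    )
    store = build_store(b, *catalog, index_date=INDEX)
    fo = store.first_occurrence
    assert len(fo) == 1
    assert fo.iloc[0]["date"] == pd.Timestamp("2010-05-01")


def test_events_after_index_excluded(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", code_p, "2016-01-05", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    assert len(store.first_occurrence) == 0
    assert store.build_log["events_after_index"] == 1


def test_prescription_prior_year_window(make_bundle, catalog):
    idx = pd.Timestamp(INDEX)
    b = make_bundle(patients=[dict(pid="p1"), dict(pid="p2")],
                    rx=[("p1", "aspirin", idx - pd.Timedelta(days=400)),
                        ("p2", "aspirin", idx - pd.Timedelta(days=100))])
    store = build_store(b, *catalog, index_date=INDEX)
    flagged = set(zip(store.rx_flags["patient_id"], store.rx_flags["drug"]))
    assert flagged == {("p2", "aspirin")}
    assert store.build_log["rx_outside_window"] == 1


def test_two_year_registration_rule(make_bundle, catalog):
    b = make_bundle(patients=[dict(pid="p1", registration="2014-06-01"),
                              dict(pid="p2", registration="2013-11-30"),
                              dict(pid="p3", registration="2013-12-01")])
    store = build_store(b, *catalog, index_date=INDEX)
    assert set(store.patients["patient_id"]) == {"p2"}
    assert store.build_log["patients_dropped_registration"] == 2


def test_unknown_codes_tallied_not_fatal(make_bundle, catalog):
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", "XYZ999", "2010-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    assert len(store.first_occurrence) == 0
    assert store.build_log["events_unmapped_code"] == 1


def test_malformed_dates_reported_per_record(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", code_p, "2010-01-01", "primary")])
    b.clinical_events.loc[1] = ["p1", code_p, "not-a-date", "primary"]
    store = build_store(b, *catalog, index_date=INDEX)
    assert store.build_log["events_malformed_date"] == 1
    assert len(store.first_occurrence) == 1


def test_hospital_codes_ascertain_conditions(make_bundle, catalog, gout_codes):
    _, code_h = gout_codes
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", code_h, "2011-02-03", "hospital")])
    store = build_store(b, *catalog, index_date=INDEX)
    assert index_cohort(store, "gout") == {"p1"}


def test_followup_truncated_and_censored(make_bundle, catalog):
    idx = pd.Timestamp(INDEX)
    b = make_bundle(
        patients=[dict(pid="p1"), dict(pid="p2")],
        admissions=[("p1", idx + pd.Timedelta(days=100)),
                    ("p1", idx + pd.Timedelta(days=1300)),   # beyond 3 years
                    ("p2", idx + pd.Timedelta(days=500))],   # after p2's death
        deaths=[("p2", idx + pd.Timedelta(days=400))])
    store = build_store(b, *catalog, index_date=INDEX)
    assert list(store.admissions["patient_id"]) == ["p1"]
    assert store.build_log["admissions_outside_window"] == 1
    assert store.build_log["admissions_after_death"] == 1
    assert set(store.deaths["patient_id"]) == {"p2"}


def test_index_cohort_selection(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    b = make_bundle(patients=[dict(pid=p) for p in ("p1", "p2", "p3")],
                    events=[("p1", code_p, "2010-01-01", "primary"),
                            ("p3", code_p, "2014-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    assert index_cohort(store, "gout") == {"p1", "p3"}


def test_index_cohort_rejects_higher_levels(small_store):
    with pytest.raises(LevelError, match="individual-level only"):
        index_cohort(small_store, "musculoskeletal conditions")
    with pytest.raises(LevelError, match="individual-level only"):
        index_cohort(small_store, "coronary heart disease")
    with pytest.raises(UnknownItemError):
        index_cohort(small_store, "dragon pox")


def test_empty_store_gives_empty_cohort(make_bundle, catalog):
    store = build_store(make_bundle(patients=[]), *catalog, index_date=INDEX)
    assert index_cohort(store, "gout") == frozenset()


def test_build_is_idempotent(small_bundle, catalog):
    a = build_store(small_bundle, *catalog, index_date=INDEX)
    b = build_store(small_bundle, *catalog, index_date=INDEX)
    for name in ("patients", "first_occurrence", "rx_flags", "admissions", "deaths"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    assert a.build_log == b.build_log


def test_post_index_events_never_change_ascertainment(make_bundle, catalog, gout_codes):
    code_p, _ = gout_codes
    base = make_bundle(patients=[dict(pid="p1")],
                       events=[("p1", code_p, "2010-01-01", "primary")])
    with_late = make_bundle(patients=[dict(pid="p1")],
                            events=[("p1", code_p, "2010-01-01", "primary"),
                                    ("p1", code_p, "2017-01-01", "primary")])
    a = build_store(base, *catalog, index_date=INDEX)
    b = build_store(with_late, *catalog, index_date=INDEX)
    pd.testing.assert_frame_equal(a.first_occurrence, b.first_occurrence)
    pd.testing.assert_frame_equal(a.rx_flags, b.rx_flags)


def test_scores_precomputed_per_patient(make_bundle, catalog):
    cond_h, _ = catalog
    mi = sorted(cond_h.codes_for("myocardial infarction", "primary"))[0]
    dm = sorted(cond_h.codes_for("diabetes", "primary"))[0]
    b = make_bundle(patients=[dict(pid="p1")],
                    events=[("p1", mi, "2010-01-01", "primary"),
                            ("p1", dm, "2011-01-01", "primary")])
    store = build_store(b, *catalog, index_date=INDEX)
    row = store.patients.iloc[0]
    assert row["charlson_score"] == 2  # MI (1) + diabetes (1)
    assert row["efi_score"] == pytest.approx(2 / 36)  # IHD + diabetes deficits
    assert row["efi_category"] == "Fit"


def test_store_persistence_round_trip(small_store, tmp_path):
    save_store(small_store, tmp_path / "store")
    loaded = load_store(tmp_path / "store")
    assert loaded.index_date == small_store.index_date
    assert loaded.build_log == small_store.build_log
    for name in ("patients", "first_occurrence", "rx_flags", "admissions", "deaths"):
        pd.testing.assert_frame_equal(getattr(loaded, name),
                                      getattr(small_store, name))
    assert loaded.condition_hierarchy.entries == \
        small_store.condition_hierarchy.entries
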