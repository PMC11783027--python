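import datetime as dt

import pandas as pd
import pytest

from cohortlens import (GeneratorConfig, RawEHRBundle, build_store, default_catalog,
                        generate, index_cohort)

INDEX_DATE = "2015-11-30"


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_bundle(catalog):
    cfg = GeneratorConfig.example(n_patients=600, seed=11)
    return generate(cfg, *catalog)


@pytest.fixture(scope="session")
def small_store(small_bundle, catalog):
    return build_store(small_bundle, *catalog, index_date=INDEX_DATE)


@pytest.fixture(scope="session")
def gout_cohort(small_store):
    return index_cohort(small_store, "gout")


def _patient(pid, age=60, gender="men", ethnicity="White", imd=1,
             registration="2005-01-01", index=INDEX_DATE):
    birth = pd.Timestamp(index) - pd.DateOffset(years=age) - pd.Timedelta(days=100)
    return {"patient_id": pid, "birth_date": birth, "gender": gender,
            "ethnicity": ethnicity, "imd_quintile": imd,
            "registration_start": pd.Timestamp(registration)}


@pytest.fixture()
def make_bundle():
    """Hand-build a tiny raw bundle from row dicts."""

    def _make(patients, events=(), rx=(), admissions=(), deaths=()):
        def frame(rows, cols):
            if not rows:
                return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            rows = [dict(zip(cols, r)) if not isinstance(r, dict) else r
                    for r in rows]
            df = pd.DataFrame(rows)
            for c in cols:
                if "date" in c:
                    df[c] = pd.to_datetime(df[c])
            return df[list(cols)]

        return RawEHRBundle(
            patients=frame([_patient(**p) if isinstance(p, dict) else p
                            for p in patients],
                           ("patient_id", "birth_date", "gender", "ethnicity",
                            "imd_quintile", "registration_start")),
            clinical_events=frame(list(events),
                                  ("patient_id", "code", "date", "source")),
            prescriptions=frame(list(rx), ("patient_id", "drug", "date")),
            admissions=frame(list(admissions), ("patient_id", "admission_date")),
            deaths=frame(list(deaths), ("patient_id", "death_date")),
        )

    return _make


@pytest.fixture()
def gout_codes(catalog):
    cond_h, _ = catalog
    return (sorted(cond_h.codes_for("gout", "primary"))[0],
            sorted(cond_h.codes_for("gout", "hospital"))[0])
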