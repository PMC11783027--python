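"""Fixed demographic strata used across generation and analysis.

All cross-tabulation in the package is demography-based: eight age bands,
gender, five ethnicity groups, deprivation quintiles (IMD, Q1 = least
deprived), and time since diagnosis (prevalent >= 1 year vs recently
incident < 1 year before the index date).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (label, lowest age, highest age) — the closed sampling/binning ranges.
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("Younger than 25", 16, 24),
    ("25-34", 25, 34),
    ("35-44", 35, 44),
    ("45-54", 45, 54),
    ("55-64", 55, 64),
    ("65-74", 65, 74),
    ("75-84", 75, 84),
    ("85 and older", 85, 100),
)

AGE_BAND_LABELS = tuple(label for label, _, _ in AGE_BANDS)

GENDERS = ("men", "women")
GENDER_LABELS = {"men": "Men", "women": "Women"}

ETHNICITY_GROUPS = ("Black", "Chinese or Mixed or Other", "South Asian",
                    "White", "Missing")

IMD_QUINTILES = (1, 2, 3, 4, 5)
IMD_LABELS = {1: "Q1 (least deprived)", 2: "Q2", 3: "Q3", 4: "Q4",
              5: "Q5 (most deprived)"}

TIME_SINCE_DIAGNOSIS_LABELS = ("1 or greater", "Less than 1")


def age_band_of(ages: pd.Series | np.ndarray) -> pd.Series:
    """Band label per integer age; ages outside the sampling ranges fall
    into the nearest boundary band."""
    index = ages.index if isinstance(ages, pd.Series) else None
    ages = pd.Series(np.asarray(ages), index=index)
    edges = [-np.inf] + [hi for _, _, hi in AGE_BANDS[:-1]] + [np.inf]
    return pd.cut(ages, bins=edges, labels=AGE_BAND_LABELS).astype(str)


def age_at(index_date: pd.Timestamp, birth_dates: pd.Series) -> pd.Series:
    """Completed years of age on *index_date*."""
    idx = pd.Timestamp(index_date)
    birth = pd.to_datetime(birth_dates)
    not_yet = (birth.dt.month * 100 + birth.dt.day) > (idx.month * 100 + idx.day)
    return (idx.year - birth.dt.year - not_yet.astype(int)).astype(int)
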