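"""Statistical disclosure control for emitted tables.

Two rules are applied to every output so that aggregate tables can leave a
secure analysis environment without manual output checking:

* every count is rounded to the nearest multiple of 10 (halves away from
  zero), so no cell reveals a small exact count;
* every percentage is an integer computed from the RAW numerator and
  denominator, then rounded (halves away from zero) — never recomputed
  from the rounded counts.

The second rule is the consequential one: a raw cell of 4 patients out of
a stratum of 50 discloses as "0 (8)" — the count is suppressed to 0 but
the percentage still reflects the true ratio, leaving prevalence estimates
unbiased.  Rounding therefore perturbs any count by at most 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tables import RawTable


def round_count(n: int) -> int:
    """Nearest multiple of 10, halves away from zero; n must be >= 0."""
    n = int(n)
    if n < 0:
        raise ValueError(f"counts must be non-negative, got {n}")
    return (n + 5) // 10 * 10


def disclosed_percent(numerator_raw: int, denominator_raw: int) -> int | None:
    """round(100 * num / den) to the nearest integer, halves away from zero,
    computed in exact integer arithmetic from RAW counts.  A zero
    denominator yields None (percentage absent, not 0)."""
    num, den = int(numerator_raw), int(denominator_raw)
    if num < 0 or den < 0:
        raise ValueError("raw counts must be non-negative")
    if den == 0:
        return None
    if num > den:
        raise ValueError(f"numerator {num} exceeds denominator {den}")
    return (200 * num + den) // (2 * den)


@dataclass
class DisclosedTable:
    """A table after disclosure control.

    ``counts`` are multiples of 10; ``percents`` holds integers or pd.NA
    where the percentage is undefined; ``cells`` holds display strings like
    ``"20,540 (61)"``.  The raw source table is retained (privately) so
    that disclosing again is an exact no-op.
    """

    name: str
    counts: pd.DataFrame
    percents: pd.DataFrame
    cells: pd.DataFrame
    percent_orientation: dict[str, str] = field(default_factory=dict)
    _raw: RawTable | None = None

    def footnote(self) -> str:
        orient = "; ".join(f"{fam}: {desc}"
                           for fam, desc in self.percent_orientation.items())
        note = ("For disclosure control, all numbers are rounded to the nearest 10 "
                "and percentages are rounded to discrete numbers computed from "
                "unrounded counts, so totals may not add up exactly to 100%.")
        return f"{note} Percentage orientation — {orient}" if orient else note

    def to_long(self) -> pd.DataFrame:
        """Machine-readable long form: family, stratum, column, count, percent."""
        rows = []
        for (fam, stratum) in self.counts.index:
            for col in self.counts.columns:
                pct = self.percents.loc[(fam, stratum), col]
                rows.append({"family": fam, "stratum": stratum, "column": col,
                             "count": int(self.counts.loc[(fam, stratum), col]),
                             "percent": None if pd.isna(pct) else int(pct),
                             "cell": self.cells.loc[(fam, stratum), col]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"name": self.name,
                   "percent_orientation": self.percent_orientation,
                   "footnote": self.footnote(),
                   "cells": self.to_long().to_dict(orient="records")}
        pd.Series(payload).to_json(path)  # type: ignore[arg-type]


def _format_cell(count: int, pct) -> str:
    return f"{count:,}" if pd.isna(pct) else f"{count:,} ({int(pct)})"


def disclose(table: RawTable | DisclosedTable) -> DisclosedTable:
    """Apply both disclosure rules to a raw table.

    Disclosing an already-disclosed table returns an identical result
    (idempotence), because percentages are always recomputed from the
    retained raw values.
    """
    if isinstance(table, DisclosedTable):
        if table._raw is None:
            return table
        return disclose(table._raw)
    counts = table.counts.map(round_count)
    pct = pd.DataFrame(pd.NA, index=table.counts.index,
                       columns=table.counts.columns, dtype=object)
    for idx in table.counts.index:
        for col in table.counts.columns:
            p = disclosed_percent(table.counts.loc[idx, col],
                                  table.denominators.loc[idx, col])
            pct.loc[idx, col] = pd.NA if p is None else p
    cells = pd.DataFrame(
        [[_format_cell(counts.loc[idx, col], pct.loc[idx, col])
          for col in counts.columns] for idx in counts.index],
        index=counts.index, columns=counts.columns)
    return DisclosedTable(name=table.name, counts=counts, percents=pct,
                          cells=cells,
                          percent_orientation=dict(table.percent_orientation),
                          _raw=table)
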