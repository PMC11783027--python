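"""Raw stratified count tables.

Every analysis output is a :class:`RawTable`: integer counts indexed by
(stratum family, stratum label) with named columns, plus a parallel frame
of raw denominators that fixes, cell by cell, which ratio the disclosed
percentage reports.  Carrying the denominator explicitly is what lets the
disclosure step compute percentages from raw values rather than from
rounded counts, and what the ``percent_orientation`` tag documents for
human readers (column percentages within a stratum family, row percentages
against a stratum total, and so on).

A denominator of 0 marks a cell whose percentage is undefined and will be
disclosed as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class RawTable:
    """Stratified raw counts with per-cell percentage denominators."""

    name: str
    counts: pd.DataFrame
    denominators: pd.DataFrame
    percent_orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.denominators.index) or \
                list(self.counts.columns) != list(self.denominators.columns):
            raise ValueError("counts and denominators must share shape and labels")
        if (self.counts.to_numpy() < 0).any() or (self.denominators.to_numpy() < 0).any():
            raise ValueError("counts and denominators must be non-negative")

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(self.counts.index.get_level_values(0)))

    def family(self, name: str) -> pd.DataFrame:
        """Counts of one stratum family."""
        return self.counts.loc[name]


def make_table(name: str,
               rows: list[tuple[str, str]],
               columns: list[str],
               counts: dict[tuple[str, str, str], int],
               denominators: dict[tuple[str, str, str], int],
               percent_orientation: dict[str, str] | None = None) -> RawTable:
    """Assemble a RawTable from sparse (family, stratum, column) -> value maps."""
    index = pd.MultiIndex.from_tuples(rows, names=["family", "stratum"])
    cdf = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    ddf = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for (fam, stratum, col), v in counts.items():
        cdf.loc[(fam, stratum), col] = int(v)
    for (fam, stratum, col), v in denominators.items():
        ddf.loc[(fam, stratum), col] = int(v)
    return RawTable(name=name, counts=cdf, denominators=ddf,
                    percent_orientation=dict(percent_orientation or {}))
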