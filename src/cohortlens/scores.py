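"""Electronic frailty index (eFI) and Charlson comorbidity score.

The eFI follows the cumulative-deficit model: a fixed panel of 36 health
deficits is assessed per patient and the score is the fraction of deficits
present, ``score = deficits / 36``, a value in [0, 1].  Scores are banded
into four categories:

    Fit             score <= 0.12
    Mild frailty    0.12 < score <= 0.24
    Moderate frailty 0.24 < score <= 0.36
    Severe frailty  score > 0.36

The mapping from recorded conditions to deficits, the band cutoffs, and the
Charlson weight table are all configuration: sensible defaults ship with the
package but alternatives can be supplied.  The Charlson score is the plain
sum of weights over the conditions a patient has; no age adjustment is
applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError

N_DEFICITS = 36

#: upper bounds (inclusive) of the eFI bands, in ascending order
DEFAULT_EFI_CUTOFFS: tuple[tuple[float, str], ...] = (
    (0.12, "Fit"),
    (0.24, "Mild frailty"),
    (0.36, "Moderate frailty"),
    (float("inf"), "Severe frailty"),
)

EFI_CATEGORIES = tuple(label for _, label in DEFAULT_EFI_CUTOFFS)


@dataclass(frozen=True)
class DeficitMap:
    """The 36 deficit names plus a condition -> deficits lookup."""

    deficits: tuple[str, ...]
    condition_to_deficits: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.deficits) != N_DEFICITS:
            raise ConfigurationError(
                f"deficit panel must list exactly {N_DEFICITS} deficits, "
                f"got {len(self.deficits)}")
        unknown = {d for ds in self.condition_to_deficits.values() for d in ds} \
            - set(self.deficits)
        if unknown:
            raise ConfigurationError(f"mapping refers to unknown deficits: {sorted(unknown)}")


@dataclass(frozen=True)
class DeficitPanel:
    """Boolean presence vector over the 36 eFI deficits."""

    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.flags) != N_DEFICITS:
            raise ConfigurationError(
                f"deficit panel must have length {N_DEFICITS}, got {len(self.flags)}")


@dataclass(frozen=True)
class EfiResult:
    score: float
    category: str


def _data(name: str) -> Path:
    return Path(resources.files("cohortlens.data") / name)  # type: ignore[arg-type]


def load_deficit_map(path: str | Path | None = None) -> DeficitMap:
    """Read a deficit,condition CSV; blank condition rows declare a deficit
    with no mapped condition in the current catalog."""
    path = _data("efi_deficits.csv") if path is None else Path(path)
    deficits: list[str] = []
    mapping: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            d = row["deficit"].strip()
            if d not in deficits:
                deficits.append(d)
            cond = row["condition"].strip()
            if cond:
                mapping.setdefault(cond, set()).add(d)
    return DeficitMap(deficits=tuple(deficits),
                      condition_to_deficits={c: frozenset(v) for c, v in mapping.items()})


def load_charlson_weights(path: str | Path | None = None) -> dict[str, int]:
    """Read a condition,weight CSV of Charlson weights."""
    path = _data("charlson_weights.csv") if path is None else Path(path)
    weights: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            weights[row["condition"].strip()] = int(row["weight"])
    _check_weights(weights)
    return weights


def _check_weights(weight_table: Mapping[str, int]) -> None:
    bad = {c: w for c, w in weight_table.items() if w < 0}
    if bad:
        raise ConfigurationError(f"negative Charlson weights: {bad}")


def panel_from_conditions(conditions: Iterable[str], deficit_map: DeficitMap) -> DeficitPanel:
    """Derive the deficit panel implied by a set of recorded conditions."""
    present: set[str] = set()
    for cond in conditions:
        present |= deficit_map.condition_to_deficits.get(cond, frozenset())
    return DeficitPanel(flags=tuple(d in present for d in deficit_map.deficits))


def compute_efi(panel: DeficitPanel,
                cutoffs: tuple[tuple[float, str], ...] = DEFAULT_EFI_CUTOFFS) -> EfiResult:
    """Score = deficits present / 36, banded by *cutoffs* (upper bounds
    inclusive, ascending; the last bound may be infinite)."""
    score = sum(panel.flags) / N_DEFICITS
    return EfiResult(score=score, category=categorise_efi(score, cutoffs))


def categorise_efi(score: float,
                   cutoffs: tuple[tuple[float, str], ...] = DEFAULT_EFI_CUTOFFS) -> str:
    if not 0 <= score <= 1:
        raise ConfigurationError(f"eFI score {score} outside [0, 1]")
    for bound, label in cutoffs:
        if score <= bound:
            return label
    raise ConfigurationError("eFI cutoffs do not cover [0, 1]")


def compute_charlson(conditions: Iterable[str], weight_table: Mapping[str, int]) -> int:
    """Sum of weights over the distinct present conditions; conditions not in
    the weight table contribute 0."""
    _check_weights(weight_table)
    return int(sum(weight_table.get(c, 0) for c in set(conditions)))


def efi_scores_vector(deficit_counts: np.ndarray) -> np.ndarray:
    """Vectorised score for per-patient deficit counts."""
    return np.asarray(deficit_counts, dtype=float) / N_DEFICITS
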