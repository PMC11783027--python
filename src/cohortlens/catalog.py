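"""Three-level condition and drug hierarchies with clinical code lists.

Conditions are organised as body system > condition group > individual
condition (e.g. cancers > hematological cancers > Hodgkin lymphoma); drugs
follow the British National Formulary layering of chapter > class >
individual drug (e.g. "02 cardiovascular system" > thiazide diuretics >
bendroflumethiazide).  Each individual item has exactly one parent at each
level, so the structures are trees and resolution to an ancestor label is
unambiguous.

Code lists attach sets of clinical codes to individual conditions, kept
separately per source dialect: ``primary`` for primary-care records and
``hospital`` for hospital records.  Codes are treated as opaque strings.

A small exemplar catalog ships with the package (see :func:`default_catalog`);
its code lists are synthetic stand-ins for published phenotype code lists,
but the loaders accept arbitrarily large catalogs of the same CSV shape.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CatalogError, LevelError, UnknownItemError

LEVELS = ("individual", "group", "top")

#: accepted aliases for hierarchy levels, per kind
_CONDITION_ALIASES = {"condition": "individual", "condition group": "group",
                      "body system": "top", "body_system": "top"}
_DRUG_ALIASES = {"drug": "individual", "class": "group", "drug class": "group",
                 "chapter": "top", "drug chapter": "top"}

CODE_SOURCES = ("primary", "hospital")


def _normalise_level(level: str, aliases: Mapping[str, str]) -> str:
    level = aliases.get(level, level)
    if level not in LEVELS:
        raise LevelError(f"unknown hierarchy level {level!r}; expected one of {LEVELS}")
    return level


class _Hierarchy:
    """Shared tree behaviour for condition and drug hierarchies."""

    entries: Mapping[str, tuple[str, str]]  # individual -> (group, top)
    _aliases: Mapping[str, str] = {}

    def __contains__(self, item: str) -> bool:
        return item in self.entries

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self.entries)

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries.values())

    @property
    def tops(self) -> frozenset[str]:
        return frozenset(t for _, t in self.entries.values())

    def resolve(self, item: str, level: str) -> str:
        """Return the ancestor label of *item* at the requested level.

        ``resolve(x, "individual")`` is the identity.  *item* must be an
        individual-level name.
        """
        level = _normalise_level(level, self._aliases)
        if item not in self.entries:
            raise UnknownItemError(f"unknown individual-level item {item!r}")
        if level == "individual":
            return item
        group, top = self.entries[item]
        return group if level == "group" else top

    def level_of(self, name: str) -> str | None:
        """Level at which *name* exists, or None if absent everywhere."""
        if name in self.entries:
            return "individual"
        if name in self.groups:
            return "group"
        if name in self.tops:
            return "top"
        return None

    def members(self, label: str, level: str) -> frozenset[str]:
        """Individual-level members of *label* at *level*."""
        level = _normalise_level(level, self._aliases)
        if level == "individual":
            if label not in self.entries:
                raise UnknownItemError(f"unknown individual-level item {label!r}")
            return frozenset({label})
        idx = 0 if level == "group" else 1
        out = frozenset(i for i, parents in self.entries.items() if parents[idx] == label)
        if not out:
            raise UnknownItemError(f"unknown {level}-level label {label!r}")
        return out

    def labels_at(self, level: str) -> frozenset[str]:
        level = _normalise_level(level, self._aliases)
        return {"individual": self.individuals, "group": self.groups,
                "top": self.tops}[level]


def _validate_tree(entries: Mapping[str, tuple[str, str]], kind: str) -> None:
    if not entries:
        raise CatalogError(f"empty {kind} catalog")
    group_parent: dict[str, str] = {}
    offenders = []
    for item, (group, top) in entries.items():
        if not item or not group or not top:
            raise CatalogError(f"{kind} entry {item!r} has a blank level label")
        if group in group_parent and group_parent[group] != top:
            offenders.append(group)
        group_parent[group] = top
    if offenders:
        raise CatalogError(
            f"{kind} groups mapped to more than one top-level label: {sorted(set(offenders))}")


@dataclass(frozen=True)
class ConditionHierarchy(_Hierarchy):
    """Body system > condition group > individual condition tree.

    ``code_lists[condition][source]`` is the set of clinical codes that
    ascertain *condition* from records of that *source* dialect.
    ``index_eligible`` lists the individual conditions that may be chosen
    as index condition (those with a non-empty code list).
    """

    entries: dict[str, tuple[str, str]]
    code_lists: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    _aliases = _CONDITION_ALIASES

    def __post_init__(self) -> None:
        _validate_tree(self.entries, "condition")
        unknown = set(self.code_lists) - set(self.entries)
        if unknown:
            raise CatalogError(f"code lists refer to unknown conditions: {sorted(unknown)}")

    @property
    def index_eligible(self) -> frozenset[str]:
        return frozenset(c for c, by_src in self.code_lists.items()
                         if any(by_src.values()))

    def code_to_condition(self) -> dict[str, str]:
        """Flat code -> condition lookup across both source dialects."""
        mapping: dict[str, str] = {}
        for cond, by_src in self.code_lists.items():
            for codes in by_src.values():
                for code in codes:
                    if mapping.get(code, cond) != cond:
                        raise CatalogError(
                            f"code {code!r} listed for both {mapping[code]!r} and {cond!r}")
                    mapping[code] = cond
        return mapping

    def codes_for(self, condition: str, source: str) -> frozenset[str]:
        if condition not in self.entries:
            raise UnknownItemError(f"unknown individual-level item {condition!r}")
        return self.code_lists.get(condition, {}).get(source, frozenset())


@dataclass(frozen=True)
class DrugHierarchy(_Hierarchy):
    """BNF-style drug chapter > drug class > individual drug tree."""

    entries: dict[str, tuple[str, str]]
    _aliases = _DRUG_ALIASES

    def __post_init__(self) -> None:
        _validate_tree(self.entries, "drug")

    @property
    def chapter_labels(self) -> frozenset[str]:
        return self.tops


def _read_csv(path: str | Path, required: Iterable[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CatalogError(f"{kind} file {path} is empty") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise CatalogError(f"{kind} file {path} lacks columns {sorted(missing)}")
    if df.empty:
        raise CatalogError(f"{kind} file {path} has no rows")
    return df


def load_condition_hierarchy(path: str | Path,
                             code_lists_path: str | Path | None = None) -> ConditionHierarchy:
    """Load a condition hierarchy from CSV (condition,group,body_system).

    Duplicate condition names, and conditions listed under two distinct
    groups, are rejected with the offending names.  An optional code-list
    CSV (condition,source,code) attaches ascertainment codes.
    """
    df = _read_csv(path, ("condition", "group", "body_system"), "condition hierarchy")
    dup_mask = df.duplicated(subset="condition", keep=False)
    if dup_mask.any():
        dupes = df.loc[dup_mask]
        conflicting = sorted(
            dupes.groupby("condition")
            .filter(lambda g: g[["group", "body_system"]].drop_duplicates().shape[0] > 1)
            ["condition"].unique())
        if conflicting:
            raise CatalogError(f"conditions mapped to more than one group: {conflicting}")
        raise CatalogError(
            f"duplicate condition rows: {sorted(dupes['condition'].unique())}")
    entries = {r.condition: (r.group, r.body_system) for r in df.itertuples()}
    code_lists: dict[str, dict[str, frozenset[str]]] = {}
    if code_lists_path is not None:
        cl = _read_csv(code_lists_path, ("condition", "source", "code"), "code list")
        bad_src = set(cl["source"]) - set(CODE_SOURCES)
        if bad_src:
            raise CatalogError(f"unknown code-list sources {sorted(bad_src)}; "
                               f"expected {CODE_SOURCES}")
        unknown = sorted(set(cl["condition"]) - set(entries))
        if unknown:
            raise CatalogError(f"code lists refer to unknown conditions: {unknown}")
        nested: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
        for r in cl.itertuples():
            nested[r.condition][r.source].add(r.code)
        code_lists = {c: {s: frozenset(codes) for s, codes in by_src.items()}
                      for c, by_src in nested.items()}
    return ConditionHierarchy(entries=entries, code_lists=code_lists)


def load_drug_hierarchy(path: str | Path) -> DrugHierarchy:
    """Load a drug hierarchy from CSV (drug,class,chapter)."""
    df = _read_csv(path, ("drug", "class", "chapter"), "drug hierarchy")
    dup_mask = df.duplicated(subset="drug", keep=False)
    if dup_mask.any():
        raise CatalogError(
            f"drugs mapped more than once: {sorted(df.loc[dup_mask, 'drug'].unique())}")
    df = df.rename(columns={"class": "drug_class"})
    entries = {r.drug: (r.drug_class, r.chapter) for r in df.itertuples()}
    return DrugHierarchy(entries=entries)


def _data_path(name: str) -> Path:
    return Path(resources.files("cohortlens.data") / name)  # type: ignore[arg-type]


def default_catalog() -> tuple[ConditionHierarchy, DrugHierarchy]:
    """The exemplar catalog shipped with the package.

    Roughly two dozen conditions and drugs spanning every hierarchy level,
    with synthetic code lists; intended for demonstration and testing, not
    as a clinically complete classification.
    """
    cond = load_condition_hierarchy(_data_path("conditions.csv"),
                                    _data_path("synthetic_code_lists.csv"))
    drug = load_drug_hierarchy(_data_path("drugs.csv"))
    return cond, drug
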