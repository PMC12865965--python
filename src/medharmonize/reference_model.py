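"""Relational reference tables, the exclusion list, and the reusable variant dictionary.

The mapping side of the pipeline is driven by five delimited tables in a
small relational schema:

* ``generics``   — generic drug names, each pointing at a therapeutic class
  (``UN``, ``GenDrugName``, ``AHFSClassID``);
* ``tradenames`` — trade/brand names resolving to a generic
  (``UN``, ``Tradename``, ``GenDrugName``);
* ``scdf``       — clinical drug-form description strings with a concept id
  and a class number (``SCDF_STR``, ``SCDF_CUI``, ``AHFSClassNum``);
* ``classes``    — the class table (``AHFSClassID``, ``AHFSClassNum``,
  ``AHFSClassText``);
* ``classes_extended`` — descriptive texts for the truncated levels of each
  class number (``AHFSClassNum``, ``AHFSClassText_2/3/4``).

Class numbers follow the four-level colon/period dialect, e.g.
``08:12.06.04``; levels 2/3/4 are prefixes of increasing depth.

The :class:`VariantDictionary` is the reusable, expert-adjudicated map from
normalized variants (brands, misspellings, abbreviations) to canonical
generic names; it persists as a diffable delimited file with per-entry
provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._io import read_delimited
from .exceptions import (
    ClassNumberParseError,
    DictionaryConflictError,
    ReferentialIntegrityError,
    SchemaError,
)
from .textnorm import normalize_text

__all__ = [
    "AHFSClassRecord",
    "AHFSReferenceSet",
    "VariantDictionary",
    "ExclusionList",
    "derive_class_levels",
    "canonical_class_num",
    "load_reference_set",
    "load_table",
    "save_dictionary",
    "load_dictionary",
    "load_exclusions",
]

_GROUP_RE = re.compile(r"^\d{2}$")


def _parse_class_num(num: str) -> list[str]:
    groups = re.split(r"[:.]", num.strip())
    if not 1 <= len(groups) <= 4 or not all(_GROUP_RE.match(g) for g in groups):
        raise ClassNumberParseError(
            f"malformed classification number {num!r}: expected 1-4 "
            "colon/period-separated 2-digit groups, e.g. '08:12.06.04'"
        )
    return groups


def canonical_class_num(num: str) -> str:
    """Re-emit a class number in the canonical dialect (``08:12.06.04``).

    The first separator is a colon, the rest periods; inputs using all
    colons or all periods are accepted and canonicalized so that joins on
    class numbers stay exact.
    """
    groups = _parse_class_num(num)
    if len(groups) == 1:
        return groups[0]
    return groups[0] + ":" + ".".join(groups[1:])


def derive_class_levels(ahfs_class_num: str) -> tuple[str, str, str]:
    """Truncated class numbers for hierarchy levels 2, 3 and 4.

    Level 2 is the first two groups, level 3 the first three, level 4 all
    four.  A shallow number (fewer groups) fills the deeper levels with its
    deepest available prefix so every class always carries three labels.

    >>> derive_class_levels("08:12.06.04")
    ('08:12', '08:12.06', '08:12.06.04')
    """
    groups = _parse_class_num(ahfs_class_num)

    def prefix(depth: int) -> str:
        return canonical_class_num(":".join(groups[: min(depth, len(groups))]))

    return prefix(2), prefix(3), prefix(4)


@dataclass(frozen=True)
class AHFSClassRecord:
    """One therapeutic class with its full and truncated-level labels."""

    ahfs_class_id: str
    ahfs_class_num: str
    ahfs_class_text: str
    level2_text: str
    level3_text: str
    level4_text: str

    @classmethod
    def from_num(
        cls, ahfs_class_id: str, ahfs_class_num: str, ahfs_class_text: str = "",
        level_texts: tuple[str, str, str] | None = None,
    ) -> "AHFSClassRecord":
        num = canonical_class_num(ahfs_class_num)
        levels = level_texts or derive_class_levels(num)
        return cls(ahfs_class_id, num, ahfs_class_text, *levels)


_SCHEMAS: dict[str, list[str]] = {
    "generics": ["UN", "GenDrugName", "AHFSClassID"],
    "tradenames": ["UN", "Tradename", "GenDrugName"],
    "scdf": ["SCDF_STR", "SCDF_CUI", "AHFSClassNum"],
    "classes": ["AHFSClassID", "AHFSClassNum", "AHFSClassText"],
    "classes_extended": [
        "AHFSClassNum", "AHFSClassText_2", "AHFSClassText_3", "AHFSClassText_4",
    ],
}


def load_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one reference table (delimiter-sniffed CSV/TSV, header required)."""
    if table not in _SCHEMAS:
        raise ValueError(f"unknown reference table {table!r}")
    df = read_delimited(path)
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: table {table!r} is missing required column(s) {missing}"
        )
    return df


@dataclass
class AHFSReferenceSet:
    """The five loaded reference tables plus derived lookup structures."""

    generics: pd.DataFrame
    tradenames: pd.DataFrame
    scdf: pd.DataFrame
    classes: pd.DataFrame
    classes_extended: pd.DataFrame

    def __post_init__(self) -> None:
        self._class_by_id: dict[str, AHFSClassRecord] = {}
        self._class_by_num: dict[str, AHFSClassRecord] = {}
        ext = {
            canonical_class_num(r.AHFSClassNum): (
                r.AHFSClassText_2, r.AHFSClassText_3, r.AHFSClassText_4,
            )
            for r in self.classes_extended.itertuples()
        }
        for r in self.classes.itertuples():
            num = canonical_class_num(r.AHFSClassNum)
            rec = AHFSClassRecord.from_num(
                str(r.AHFSClassID), num, r.AHFSClassText, ext.get(num)
            )
            self._class_by_id[rec.ahfs_class_id] = rec
            self._class_by_num[rec.ahfs_class_num] = rec

    # -- lookups ---------------------------------------------------------

    def class_by_id(self, class_id: str) -> AHFSClassRecord:
        return self._class_by_id[str(class_id)]

    def class_by_num(self, class_num: str) -> AHFSClassRecord:
        return self._class_by_num[canonical_class_num(class_num)]

    def classes_for_generic(self, gen_drug_name: str) -> list[AHFSClassRecord]:
        """All classes assigned to a generic (most drugs have exactly one)."""
        key = normalize_text(gen_drug_name)
        rows = self.generics[
            self.generics["GenDrugName"].map(normalize_text) == key
        ]
        return [self._class_by_id[str(cid)] for cid in rows["AHFSClassID"]]

    def generic_names(self) -> list[str]:
        return sorted(set(self.generics["GenDrugName"]))

    def lexicon(self) -> dict[str, str]:
        """Normalized generic *and* trade names, each → its canonical generic."""
        lex: dict[str, str] = {}
        for r in self.generics.itertuples():
            lex[normalize_text(r.GenDrugName)] = r.GenDrugName
        for r in self.tradenames.itertuples():
            lex.setdefault(normalize_text(r.Tradename), r.GenDrugName)
        return lex

    def counts(self) -> dict[str, int]:
        return {
            "generics": len(self.generics),
            "tradenames": len(self.tradenames),
            "scdf": len(self.scdf),
            "classes": len(self.classes),
            "classes_extended": len(self.classes_extended),
        }


def _check_integrity(refset: AHFSReferenceSet) -> None:
    class_ids = set(refset.classes["AHFSClassID"].astype(str))
    class_nums = {canonical_class_num(n) for n in refset.classes["AHFSClassNum"]}
    generic_names = {normalize_text(n) for n in refset.generics["GenDrugName"]}

    dangling = sorted(
        {str(c) for c in refset.generics["AHFSClassID"] if str(c) not in class_ids}
    )
    if dangling:
        raise ReferentialIntegrityError(
            f"generics reference unknown AHFSClassID(s): {dangling}", dangling
        )
    dangling = sorted(
        {
            n for n in refset.tradenames["GenDrugName"]
            if normalize_text(n) not in generic_names
        }
    )
    if dangling:
        raise ReferentialIntegrityError(
            f"tradenames reference unknown GenDrugName(s): {dangling}", dangling
        )
    dangling = sorted(
        {
            n for n in refset.scdf["AHFSClassNum"]
            if canonical_class_num(n) not in class_nums
        }
    )
    if dangling:
        raise ReferentialIntegrityError(
            f"scdf rows reference unknown AHFSClassNum(s): {dangling}", dangling
        )
    dup = refset.generics["UN"][refset.generics["UN"].duplicated()]
    if len(dup):
        raise ReferentialIntegrityError(
            f"duplicate UN key(s) in generics: {sorted(set(dup))}", sorted(set(dup))
        )


def load_reference_set(paths: Mapping[str, str | Path]) -> AHFSReferenceSet:
    """Load the five reference tables and verify every foreign key.

    ``paths`` maps table names (``generics``, ``tradenames``, ``scdf``,
    ``classes``, ``classes_extended``) to file locations.  Raises
    :class:`SchemaError` for a missing column and
    :class:`ReferentialIntegrityError` (listing the offending keys) for a
    dangling link.
    """
    missing = [t for t in _SCHEMAS if t not in paths]
    if missing:
        raise SchemaError(f"missing reference table path(s): {missing}")
    refset = AHFSReferenceSet(
        **{table: load_table(paths[table], table) for table in _SCHEMAS}
    )
    _check_integrity(refset)
    return refset


# ---------------------------------------------------------------------------
# Variant dictionary
# ---------------------------------------------------------------------------

_DICT_COLUMNS = ["variant", "canonical", "source", "date"]


@dataclass
class VariantDictionary:
    """Reusable map from normalized variant text to canonical generic name.

    Keys are already normalized (lowercase, punctuation-stripped); values
    are generic drug names.  Every entry carries provenance: a source tag
    (``seeded`` or ``expert-adjudicated``) and a decision date, so the
    dictionary remains auditable as it grows across runs.
    """

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, variant: str) -> bool:
        return normalize_text(variant) in self.entries

    def lookup(self, variant: str) -> str | None:
        return self.entries.get(normalize_text(variant))

    def add(
        self, variant: str, canonical: str,
        source: str = "expert-adjudicated", date: str = "",
    ) -> None:
        key = normalize_text(variant)
        existing = self.entries.get(key)
        if existing is not None and existing != canonical:
            raise DictionaryConflictError(
                f"variant {key!r} already maps to {existing!r}; "
                f"refusing conflicting canonical {canonical!r}"
            )
        self.entries[key] = canonical
        self.provenance.setdefault(key, (source, date))

    def keys(self) -> list[str]:
        return sorted(self.entries)


def save_dictionary(dictionary: VariantDictionary, path: str | Path) -> None:
    """Write the dictionary as sorted delimited text (lossless, diffable)."""
    rows = [
        {
            "variant": k,
            "canonical": dictionary.entries[k],
            "source": dictionary.provenance.get(k, ("", ""))[0],
            "date": dictionary.provenance.get(k, ("", ""))[1],
        }
        for k in sorted(dictionary.entries)
    ]
    pd.DataFrame(rows, columns=_DICT_COLUMNS).to_csv(path, index=False)


def load_dictionary(path: str | Path) -> VariantDictionary:
    """Load a dictionary file; conflicting duplicate keys are an error."""
    df = read_delimited(path)
    missing = [c for c in ("variant", "canonical") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: dictionary file missing column(s) {missing}")
    d = VariantDictionary()
    for r in df.itertuples():
        d.add(
            r.variant, r.canonical,
            source=getattr(r, "source", ""), date=getattr(r, "date", ""),
        )
    return d


@dataclass(frozen=True)
class ExclusionList:
    """Normalized names of OTC drugs, vitamins and supplements to drop."""

    terms: frozenset[str]

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "ExclusionList":
        return cls(frozenset(normalize_text(t) for t in terms if normalize_text(t)))


def load_exclusions(path: str | Path) -> ExclusionList:
    """Read the exclusion list (single ``term`` column)."""
    df = read_delimited(path)
    if "term" not in df.columns:
        raise SchemaError(f"{path}: exclusion file missing column 'term'")
    return ExclusionList.from_terms(df["term"])


def save_exclusions(excl: ExclusionList, path: str | Path) -> None:
    pd.DataFrame({"term": sorted(excl.terms)}).to_csv(path, index=False)
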