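"""Normalization of raw free-text medication entries and OTC/supplement filtering.

Free-text medication fields mix case at random ("lipitor" / "Lipitor"),
carry punctuation, and append dose and frequency fragments
("lisinopril/HCTZ 20-12.5 mg").  Everything downstream matches on a
canonical form: lowercased, punctuation replaced by spaces, whitespace
collapsed.  Two exceptions keep useful structure intact:

* a hyphen between two letters survives inside its token — it marks a
  combination product ("lisinopril-hctz");
* a hyphen or period between two digits survives — it keeps a dose range
  such as "20-12.5" as a single token.

Dose, unit and frequency tokens are retained (for the audit trail) but
counted and flagged so that the matching stages never treat "mg" or
"daily" as a drug-name candidate.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .reference_model import ExclusionList

__all__ = [
    "RawMedicationEntry",
    "NormalizedEntry",
    "normalize_text",
    "normalize",
    "split_combination",
    "filter_exclusions",
    "read_raw_entries",
    "write_raw_entries",
]

_PUNCT = set(string.punctuation)

# Unit / form / frequency vocabulary that never names a drug.
_UNIT_WORDS = {
    "mg", "mcg", "ug", "ml", "g", "gm", "iu", "meq", "units", "unit",
    "tab", "tabs", "tablet", "tablets", "cap", "caps", "capsule", "capsules",
    "patch", "spray", "drops", "puff", "puffs",
}
_FREQUENCY_WORDS = {
    "daily", "weekly", "nightly", "monthly", "once", "twice",
    "qd", "qhs", "bid", "tid", "qid", "prn", "po", "am", "pm", "hs",
}


def _is_dose_token(tok: str) -> bool:
    """True for purely numeric tokens, dose ranges, unit and frequency words."""
    if not tok:
        return False
    if tok in _UNIT_WORDS or tok in _FREQUENCY_WORDS:
        return True
    stripped = tok
    for unit in _UNIT_WORDS:  # "20mg", "12.5ml"
        if stripped.endswith(unit):
            stripped = stripped[: -len(unit)]
            break
    if not stripped:
        return False
    return all(c.isdigit() or c in ".-/" for c in stripped) and any(
        c.isdigit() for c in stripped
    )


@dataclass(frozen=True)
class RawMedicationEntry:
    """One participant-visit free-text medication record.

    Dose/route/frequency/date fields are carried through untouched; the
    pipeline deliberately does not parse them.
    """

    record_id: str
    participant_id: str
    visit_id: str
    raw_text: str
    dose_text: str = ""
    route_text: str = ""
    frequency_text: str = ""
    start_date_text: str = ""


@dataclass(frozen=True)
class NormalizedEntry:
    """The canonical, matchable form of one raw entry."""

    record_id: str
    norm_text: str
    tokens: tuple[str, ...]
    numeric_tokens_removed: int
    empty_input: bool = False
    raw: RawMedicationEntry | None = field(default=None, compare=False)

    @property
    def name_tokens(self) -> tuple[str, ...]:
        """Tokens that may name a drug (dose/unit/frequency tokens removed)."""
        return tuple(t for t in self.tokens if not _is_dose_token(t))

    @property
    def name_text(self) -> str:
        """The candidate drug-name string: non-dose tokens rejoined."""
        return " ".join(self.name_tokens)


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation to spaces, collapse whitespace.

    Keeps an intra-token hyphen between letters (combination marker) or
    between digits (dose range) and a period between digits (decimal dose).
    Idempotent.
    """
    lowered = text.lower()
    out: list[str] = []
    for i, c in enumerate(lowered):
        if c not in _PUNCT:
            out.append(c if not c.isspace() else " ")
            continue
        prev = lowered[i - 1] if i > 0 else ""
        nxt = lowered[i + 1] if i + 1 < len(lowered) else ""
        if c == "-" and prev.isalnum() and nxt.isalnum():
            out.append(c)
        elif c == "." and prev.isdigit() and nxt.isdigit():
            out.append(c)
        else:
            out.append(" ")
    return " ".join("".join(out).split())


def normalize(entry: RawMedicationEntry) -> NormalizedEntry:
    """Normalize one raw entry; empty input is flagged, never dropped."""
    norm = normalize_text(entry.raw_text)
    tokens = tuple(norm.split())
    return NormalizedEntry(
        record_id=entry.record_id,
        norm_text=norm,
        tokens=tokens,
        numeric_tokens_removed=sum(1 for t in tokens if _is_dose_token(t)),
        empty_input=not norm,
        raw=entry,
    )


def _split_hyphenated(token: str) -> list[str]:
    """Split a hyphenated token into components, re-joining short fragments.

    Fragments shorter than 3 characters are glued to their neighbour
    without the hyphen, so "co-codamol" yields ["cocodamol"] rather than a
    false two-drug split, while "lisinopril-hctz" yields both components.
    """
    fragments = [f for f in token.split("-") if f]
    if len(fragments) <= 1:
        return [token.replace("-", "")] if fragments else []
    merged: list[str] = []
    pending = ""
    for frag in fragments:
        if len(frag) < 3:
            pending += frag
            continue
        if pending:
            merged.append(pending + frag)
            pending = ""
        else:
            merged.append(frag)
    if pending:  # trailing short fragment glues backwards
        if merged:
            merged[-1] = merged[-1] + pending
        else:
            merged.append(pending)
    return merged


def split_combination(norm: NormalizedEntry) -> list[str]:
    """Component name candidates of a (possibly combination) entry.

    The first element is the primary active ingredient — combination
    products are classified by it.  Single-ingredient entries return a
    one-element list; dose tokens never produce components.
    """
    components: list[str] = []
    for token in norm.name_tokens:
        components.extend(_split_hyphenated(token))
    return components


_RAW_COLUMNS = {
    "record_id": "record_id",
    "participant_id": "participant_id",
    "visit_id": "visit_id",
    "med_text": "raw_text",
    "dose": "dose_text",
    "route": "route_text",
    "frequency": "frequency_text",
    "start_date": "start_date_text",
}


def read_raw_entries(path) -> list[RawMedicationEntry]:
    """Read raw medication records from a delimited file with headers.

    Required columns: record_id, participant_id, visit_id, med_text.
    Optional dose/route/frequency/start_date columns are carried through;
    anything else is ignored.
    """
    from ._io import read_delimited
    from .exceptions import SchemaError

    df = read_delimited(path)
    required = ["record_id", "participant_id", "visit_id", "med_text"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: raw records missing column(s) {missing}")
    entries = []
    for row in df.itertuples():
        kwargs = {
            field_name: getattr(row, col, "")
            for col, field_name in _RAW_COLUMNS.items()
        }
        entries.append(RawMedicationEntry(**kwargs))
    return entries


def write_raw_entries(entries: Sequence[RawMedicationEntry], path) -> None:
    """Write raw records in the same delimited layout ``read_raw_entries`` expects."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "participant_id": e.participant_id,
                "visit_id": e.visit_id,
                "med_text": e.raw_text,
                "dose": e.dose_text,
                "route": e.route_text,
                "frequency": e.frequency_text,
                "start_date": e.start_date_text,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


ExclusionMode = Literal["exact", "token", "exact+token"]


def _exclusion_hit(
    norm: NormalizedEntry, terms: frozenset[str] | set[str], mode: ExclusionMode
) -> str | None:
    """The exclusion term this entry matches, or None."""
    if mode in ("exact", "exact+token"):
        if norm.norm_text in terms:
            return norm.norm_text
        if norm.name_text and norm.name_text in terms:
            return norm.name_text
    if mode in ("token", "exact+token"):
        for tok in norm.name_tokens:
            if tok in terms:
                return tok
    return None


def filter_exclusions(
    entries: Sequence[NormalizedEntry],
    excl: "ExclusionList",
    mode: ExclusionMode = "exact+token",
) -> tuple[list[NormalizedEntry], list[tuple[NormalizedEntry, str]]]:
    """Partition entries into (eligible, excluded) against the OTC/supplement list.

    An entry is excluded iff the whole normalized name, the dose-stripped
    name, or (in token mode) any single non-dose token equals an exclusion
    term.  The partition is total: every input lands in exactly one side.
    Excluded entries are returned with the term they matched, for the
    exclusions report.
    """
    terms = set(excl.terms)
    if not terms:
        warnings.warn(
            "exclusion filtering enabled with an empty exclusion list",
            stacklevel=2,
        )
    eligible: list[NormalizedEntry] = []
    excluded: list[tuple[NormalizedEntry, str]] = []
    for entry in entries:
        term = _exclusion_hit(entry, terms, mode)
        if term is None:
            eligible.append(entry)
        else:
            excluded.append((entry, term))
    return eligible, excluded
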