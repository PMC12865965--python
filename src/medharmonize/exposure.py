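"""Phase 3 — long medication-class pairings and the wide binary exposure matrix.

Standardized and classified records are first laid out long — one row per
participant, visit, medication and assigned class — and then pivoted wide:
one row per (participant, visit), one binary column per therapeutic class.
A cell is 1 iff at least one medication of that class was reported at that
visit, so several drugs of the same class (simvastatin + atorvastatin)
collapse into a single indicator.

A declarative merge map (from_class → to_class) consolidates
pharmacologically similar classes before pivoting, and columns can be
rolled up from the full four-level class number to level 2 or 3.
Participant-visits with no eligible medication appear as all-zero rows
only when a visit roster is supplied — absence of a row is otherwise
indistinguishable from no data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._io import read_delimited
from .class_mapper import ClassificationMap
from .exceptions import ConfigurationError, SchemaError, ValidationError
from .reference_model import canonical_class_num, derive_class_levels
from .standardizer import MatchResult

__all__ = [
    "to_long",
    "to_wide",
    "summarize_exposure",
    "load_merge_map",
    "resolve_merges",
    "write_wide_csv",
]

LONG_COLUMNS = [
    "participant_id", "visit_id", "canonical_name", "AHFSClassNum", "class_label",
]


def to_long(
    results: Sequence[MatchResult], classmap: ClassificationMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format medication-class pairings plus a side table of leftovers.

    One row per resolved record per assigned class, deterministically
    ordered by (participant, visit, name, class).  Records without a
    canonical name or without a class assignment go to the side table —
    they are reported, never silently dropped.  A resolved record lacking
    participant/visit keys is a validation error.
    """
    rows = []
    side = []
    for r in results:
        if r.canonical_name is None:
            side.append(
                {"record_id": r.record_id, "reason": f"status={r.status}"}
            )
            continue
        if r.entry is None or r.entry.raw is None:
            raise ValidationError(
                f"record {r.record_id} lacks participant/visit keys"
            )
        raw = r.entry.raw
        assignments = classmap.get(r.canonical_name)
        if not assignments:
            side.append(
                {"record_id": r.record_id, "reason": "no class assignment"}
            )
            continue
        for a in assignments:
            rows.append(
                {
                    "participant_id": raw.participant_id,
                    "visit_id": raw.visit_id,
                    "canonical_name": r.canonical_name,
                    "AHFSClassNum": a.ahfs_class_num,
                    "class_label": a.ahfs_class_text,
                }
            )
    long_df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    long_df = (
        long_df.drop_duplicates()
        .sort_values(LONG_COLUMNS)
        .reset_index(drop=True)
    )
    side_df = pd.DataFrame(side, columns=["record_id", "reason"])
    return long_df, side_df


def load_merge_map(path: str | Path) -> dict[str, str]:
    """Read a subclass merge map (from_num, to_num[, rationale])."""
    df = read_delimited(path)
    missing = [c for c in ("from_num", "to_num") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: merge map missing column(s) {missing}")
    return {
        canonical_class_num(r.from_num): canonical_class_num(r.to_num)
        for r in df.itertuples()
    }


def resolve_merges(merge_map: Mapping[str, str]) -> dict[str, str]:
    """Flatten transitive merge chains; a cycle is a configuration error."""
    resolved: dict[str, str] = {}
    for start in merge_map:
        seen = [start]
        node = start
        while node in merge_map:
            node = merge_map[node]
            if node in seen:
                raise ConfigurationError(
                    f"merge-map cycle: {' -> '.join(seen + [node])}"
                )
            seen.append(node)
        resolved[start] = node
    return resolved


def _rollup(num: str, level: int) -> str:
    if level == 4:
        return canonical_class_num(num)
    l2, l3, _l4 = derive_class_levels(num)
    return {2: l2, 3: l3}[level]


def to_wide(
    long_df: pd.DataFrame,
    class_universe: Sequence[str] | None = None,
    merge_map: Mapping[str, str] | None = None,
    roster: pd.DataFrame | None = None,
    level: int = 4,
) -> pd.DataFrame:
    """Pivot long rows into the participant×visit binary exposure matrix.

    Index: (participant_id, visit_id); columns: class numbers at the
    requested hierarchy level (post-merge); cells are 0/1.  ``class_universe``
    fixes the column set (it must cover every observed class); a roster
    adds all-zero rows for medication-free visits.
    """
    if level not in (2, 3, 4):
        raise ConfigurationError(f"column granularity level must be 2, 3 or 4")
    resolved = resolve_merges(merge_map or {})

    def target_class(num: str) -> str:
        num = canonical_class_num(num)
        return _rollup(resolved.get(num, num), level)

    observed: set[str] = set()
    keys: set[tuple[str, str]] = set()
    cells: set[tuple[str, str, str]] = set()
    for r in long_df.itertuples():
        cls = target_class(r.AHFSClassNum)
        observed.add(cls)
        keys.add((str(r.participant_id), str(r.visit_id)))
        cells.add((str(r.participant_id), str(r.visit_id), cls))

    if class_universe is not None:
        universe = sorted({_rollup(canonical_class_num(c), level)
                           for c in class_universe})
        uncovered = observed - set(universe)
        if uncovered:
            raise ValidationError(
                f"class universe does not cover observed classes: "
                f"{sorted(uncovered)}"
            )
    else:
        universe = sorted(observed)

    if roster is not None:
        missing = [c for c in ("participant_id", "visit_id")
                   if c not in roster.columns]
        if missing:
            raise SchemaError(f"visit roster missing column(s) {missing}")
        keys |= {
            (str(r.participant_id), str(r.visit_id))
            for r in roster.itertuples()
        }

    index = pd.MultiIndex.from_tuples(
        sorted(keys), names=["participant_id", "visit_id"]
    )
    matrix = pd.DataFrame(0, index=index, columns=universe, dtype="int8")
    for pid, vid, cls in cells:
        matrix.loc[(pid, vid), cls] = 1
    return matrix


def summarize_exposure(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-class prevalence (column means) and per-visit class counts (row sums).

    Row sums are a class-level polypharmacy proxy: how many distinct
    therapeutic classes a participant was exposed to at a visit.
    """
    bad = matrix.values[(matrix.values != 0) & (matrix.values != 1)]
    if bad.size:
        raise ValidationError("exposure matrix cells must be 0 or 1")
    prevalence = matrix.mean(axis=0)
    prevalence.name = "prevalence"
    burden = matrix.sum(axis=1)
    burden.name = "n_classes"
    return prevalence, burden


def _sanitize(text: str) -> str:
    return "_".join("".join(c if c.isalnum() else " " for c in text).split())


def write_wide_csv(
    matrix: pd.DataFrame,
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Write the wide matrix with columns labeled class-num + sanitized text."""
    out = matrix.copy()
    if labels:
        out.columns = [
            f"{c}_{_sanitize(labels[c])}" if c in labels and labels[c] else c
            for c in out.columns
        ]
    out.reset_index().to_csv(path, index=False)
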