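"""Phase 2 — mapping standardized generic names to therapeutic classes.

Unique standardized names are resolved sequentially: exact match against
the generic-name table, exact match against trade names (resolved through
their generic), then Levenshtein fuzzy match (threshold >= 0.90,
inclusive) against clinical-drug-form description strings.  Names that
survive all three stages go to the expert queue.  Every assignment is
recorded in a persistent classification map so repeat names are never
recomputed, and carries the full four-level class hierarchy.

A drug legitimately belonging to several classes yields one assignment
per class; the downstream exposure matrix sets all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from ._io import read_delimited
from .audit_report import AuditLog, StageCounts
from .exceptions import ReferentialIntegrityError, SchemaError, ValidationError
from .reference_model import AHFSReferenceSet, canonical_class_num
from .string_metrics import SimilarityScore, levenshtein_similarity
from .textnorm import normalize_text

__all__ = [
    "ClassAssignment",
    "ClassificationMap",
    "ClassMapperConfig",
    "map_generic_exact",
    "map_trade_name",
    "map_fuzzy_scdf",
    "classify_all",
    "calibrate_threshold",
]

MapMethod = Literal["generic_exact", "trade_name", "fuzzy_scdf", "expert"]

PHASE2 = "Phase 2: Therapeutic Class Mapping"

# Dose-form / strength words stripped from drug-form description strings
# before fuzzy scoring, since self-reported names rarely carry them.
_FORM_WORDS = {
    "oral", "tablet", "tablets", "capsule", "capsules", "solution",
    "suspension", "injection", "injectable", "topical", "cream", "ointment",
    "patch", "spray", "syrup", "mg", "mcg", "ml",
}


@dataclass(frozen=True)
class ClassAssignment:
    """One standardized name bound to one therapeutic class (all four levels)."""

    canonical_name: str
    ahfs_class_num: str
    ahfs_class_text: str
    level2_text: str
    level3_text: str
    level4_text: str
    method: MapMethod
    score: SimilarityScore | None = None


@dataclass
class ClassificationMap:
    """Persistent name → class assignments, reusable across runs."""

    entries: dict[str, list[ClassAssignment]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return normalize_text(name) in self.entries

    def get(self, name: str) -> list[ClassAssignment] | None:
        return self.entries.get(normalize_text(name))

    def put(self, name: str, assignments: list[ClassAssignment]) -> None:
        self.entries[normalize_text(name)] = assignments

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        rows = []
        for name in sorted(self.entries):
            for a in self.entries[name]:
                rows.append(
                    {
                        "name": name,
                        "canonical_name": a.canonical_name,
                        "AHFSClassNum": a.ahfs_class_num,
                        "AHFSClassText": a.ahfs_class_text,
                        "level2": a.level2_text,
                        "level3": a.level3_text,
                        "level4": a.level4_text,
                        "method": a.method,
                        "score_pct": a.score.percent if a.score else "",
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "name", "canonical_name", "AHFSClassNum", "AHFSClassText",
                "level2", "level3", "level4", "method", "score_pct",
            ],
        ).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ClassificationMap":
        df = read_delimited(path)
        required = ["canonical_name", "AHFSClassNum", "method"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: classmap missing column(s) {missing}")
        cmap = cls()
        for r in df.itertuples():
            score = None
            if r.score_pct:
                score = SimilarityScore(float(r.score_pct) / 100.0, "levenshtein")
            a = ClassAssignment(
                r.canonical_name, canonical_class_num(r.AHFSClassNum),
                r.AHFSClassText, r.level2, r.level3, r.level4,
                r.method, score,
            )
            key = getattr(r, "name", "") or r.canonical_name
            cmap.entries.setdefault(normalize_text(key), []).append(a)
        return cmap


@dataclass(frozen=True)
class ClassMapperConfig:
    fuzzy_threshold: float = 0.90
    strip_form_words: bool = True


def _assign(
    refset: AHFSReferenceSet, canonical: str, method: MapMethod,
    score: SimilarityScore | None = None,
) -> list[ClassAssignment]:
    records = refset.classes_for_generic(canonical)
    if not records:
        raise ReferentialIntegrityError(
            f"generic {canonical!r} matched but its class key does not resolve"
        )
    return [
        ClassAssignment(
            canonical, rec.ahfs_class_num, rec.ahfs_class_text,
            rec.level2_text, rec.level3_text, rec.level4_text, method, score,
        )
        for rec in records
    ]


def map_generic_exact(
    name: str, refset: AHFSReferenceSet
) -> list[ClassAssignment] | None:
    """Exact (case/punctuation-normalized) match against generic drug names."""
    key = normalize_text(name)
    hit = next(
        (
            g for g in refset.generics["GenDrugName"]
            if normalize_text(g) == key
        ),
        None,
    )
    if hit is None:
        return None
    return _assign(refset, hit, "generic_exact")


def map_trade_name(
    name: str, refset: AHFSReferenceSet
) -> list[ClassAssignment] | None:
    """Exact match against trade names, resolved through their generic.

    A trade name pointing at two generics with *different* classes is an
    ambiguity the automated stage must not resolve; it raises
    :class:`ValidationError` so the caller can queue the name for review.
    """
    key = normalize_text(name)
    generics = sorted(
        {
            r.GenDrugName
            for r in refset.tradenames.itertuples()
            if normalize_text(r.Tradename) == key
        }
    )
    if not generics:
        return None
    if len(generics) > 1:
        nums = {
            rec.ahfs_class_num
            for g in generics
            for rec in refset.classes_for_generic(g)
        }
        if len(nums) > 1:
            raise ValidationError(
                f"trade name {name!r} resolves to multiple generics with "
                f"different classes: {generics}"
            )
    return _assign(refset, generics[0], "trade_name")


def _scdf_target(scdf_str: str, strip_form_words: bool) -> str:
    norm = normalize_text(scdf_str)
    if not strip_form_words:
        return norm
    kept = [t for t in norm.split() if t not in _FORM_WORDS and not t.isdigit()]
    return " ".join(kept) or norm


def map_fuzzy_scdf(
    name: str,
    refset: AHFSReferenceSet,
    threshold: float = 0.90,
    strip_form_words: bool = True,
) -> list[ClassAssignment] | None:
    """Levenshtein fuzzy match against clinical-drug-form description strings.

    The best-scoring form string wins iff its similarity meets the
    threshold and it is a unique top; a tie between form strings carrying
    different classes raises :class:`ValidationError` (expert queue).
    """
    key = normalize_text(name)
    scored: list[tuple[float, str, str]] = []  # (score, target, class_num)
    for r in refset.scdf.itertuples():
        target = _scdf_target(r.SCDF_STR, strip_form_words)
        s = levenshtein_similarity(key, target)
        scored.append((s.value, r.SCDF_STR, canonical_class_num(r.AHFSClassNum)))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1]))
    top_score = scored[0][0]
    if top_score < threshold:
        return None
    tied = [t for t in scored if t[0] == top_score]
    classes = sorted({t[2] for t in tied})
    if len(classes) > 1:
        raise ValidationError(
            f"name {name!r} fuzzy-ties multiple drug-form strings with "
            f"different classes: {classes}"
        )
    rec = refset.class_by_num(classes[0])
    score = SimilarityScore(top_score, "levenshtein")
    return [
        ClassAssignment(
            name, rec.ahfs_class_num, rec.ahfs_class_text,
            rec.level2_text, rec.level3_text, rec.level4_text,
            "fuzzy_scdf", score,
        )
    ]


def classify_all(
    unique_names: Sequence[str],
    refset: AHFSReferenceSet,
    classmap: ClassificationMap | None = None,
    cfg: ClassMapperConfig | None = None,
    audit: AuditLog | None = None,
) -> tuple[ClassificationMap, list[str], list[StageCounts]]:
    """Classify deduplicated standardized names through the three stages.

    Known names are served from the persistent ``classmap`` without
    recomputation.  Returns the grown map, the unresolved (expert-queue)
    names, and per-stage counts whose denominators are the number of
    unique input names.
    """
    cfg = cfg or ClassMapperConfig()
    classmap = classmap if classmap is not None else ClassificationMap()
    names = [n for n in dict.fromkeys(unique_names) if n and normalize_text(n)]
    phase_total = len(names)

    pending = []
    for name in names:
        if name not in classmap:
            pending.append(name)

    stage_counts: list[StageCounts] = []
    unresolved: list[str] = []
    n_cached = phase_total - len(pending)

    stages: list[tuple[str, int]] = [
        ("1. Direct Matching to Generic Names", 1),
        ("2. Matching Trade Names", 2),
        ("3. Fuzzy Match to Drug-Form Strings", 3),
    ]
    for label, stage in stages:
        n_in = len(pending)
        still: list[str] = []
        n_correct = 0
        n_queued = 0
        for name in pending:
            try:
                if stage == 1:
                    assignments = map_generic_exact(name, refset)
                elif stage == 2:
                    assignments = map_trade_name(name, refset)
                else:
                    assignments = map_fuzzy_scdf(
                        name, refset, cfg.fuzzy_threshold, cfg.strip_form_words
                    )
            except ValidationError:
                unresolved.append(name)
                n_queued += 1
                continue
            if assignments is None:
                still.append(name)
                continue
            classmap.put(name, assignments)
            n_correct += 1
            if audit is not None:
                audit.append(
                    name, PHASE2, stage, "classify",
                    before="unclassified", after=assignments[0].method,
                    score_pct=(
                        assignments[0].score.percent
                        if assignments[0].score else None
                    ),
                )
        stage_counts.append(
            StageCounts(
                PHASE2, label, n_correct, n_queued,
                n_in - n_correct - n_queued, n_in, phase_total,
            )
        )
        pending = still

    unresolved.extend(pending)
    # stable, deduplicated expert queue
    unresolved = list(dict.fromkeys(unresolved))
    if n_cached and audit is not None:
        audit.append(
            "-", PHASE2, 0, "cache",
            before=f"{n_cached} names", after="served from classification map",
        )
    return classmap, unresolved, stage_counts


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

Band = tuple[float, float]
DEFAULT_BANDS: tuple[Band, ...] = ((0.86, 0.90), (0.90, 0.95), (0.95, 1.0001))


def calibrate_threshold(
    labeled: pd.DataFrame,
    bands: Sequence[Band] = DEFAULT_BANDS,
    per_band: int = 5,
    precision_target: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Band-wise precision from expert-labeled fuzzy matches; recommend a threshold.

    ``labeled`` needs columns ``score`` (similarity in [0, 1]) and
    ``accepted`` (expert accept/reject).  Up to ``per_band`` candidates are
    sampled per similarity band (seeded, without replacement), precision
    is computed per band, and the recommendation is the lowest band edge
    from which every band at or above it meets the precision target.
    Empty bands are reported as no-data rows.
    """
    for col in ("score", "accepted"):
        if col not in labeled.columns:
            raise SchemaError(f"labeled sample missing column {col!r}")
    rows = []
    precisions: list[float | None] = []
    for lo, hi in bands:
        in_band = labeled[(labeled["score"] >= lo) & (labeled["score"] < hi)]
        if len(in_band) == 0:
            rows.append(
                {"band_low": lo, "band_high": hi, "n_sampled": 0, "precision": None}
            )
            precisions.append(None)
            continue
        n = min(per_band, len(in_band))
        sample = in_band.sample(n=n, random_state=seed)
        prec = float(sample["accepted"].astype(bool).mean())
        rows.append(
            {"band_low": lo, "band_high": hi, "n_sampled": n, "precision": prec}
        )
        precisions.append(prec)
    table = pd.DataFrame(rows)

    recommended = bands[-1][0]
    for i, (lo, _hi) in enumerate(bands):
        higher = [p for p in precisions[i:] if p is not None]
        if higher and all(p >= precision_target for p in higher):
            recommended = lo
            break
    return table, float(recommended)
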