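"""Phase 1 — staged standardization of free-text entries to generic drug names.

Entries flow through four automated stages, each seeing only what the
previous stage left unmatched:

1. absolute match against the generic + trade-name lexicon;
2. spelling-tolerant fuzzy match (character-n-gram Jaccard by default);
3. absolute lookup in the expert-curated variant dictionary;
4. fuzzy lookup over the dictionary keys.

An entry resolving to two or more *distinct* generics is ambiguous; a
fuzzy score in the borderline band [0.85, 0.90) is held for review.  Both
are frozen at first flagging — uncertainty never propagates into later
automated stages — and wait in queues for expert adjudication (stage 5),
whose accepted decisions grow the reusable dictionary.

Combination products (hyphen-joined components, "lisinopril-hctz") are
resolved to their primary active ingredient and are *not* ambiguous; two
distinct free-standing drug names in one entry are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import pandas as pd

from ._io import read_delimited
from .audit_report import AuditLog, StageCounts
from .exceptions import ConfigurationError, SchemaError, ValidationError
from .reference_model import VariantDictionary
from .string_metrics import (
    CandidateMatch,
    SimilarityScore,
    jaccard_ngram,
    levenshtein_similarity,
)
from .textnorm import NormalizedEntry, split_combination

__all__ = [
    "MatchResult",
    "StandardizationConfig",
    "CorpusStandardization",
    "ExpertDecision",
    "absolute_match",
    "fuzzy_match_stage",
    "dictionary_match",
    "standardize_corpus",
    "apply_expert_decisions",
    "load_decisions",
    "results_frame",
]

Status = Literal[
    "matched", "ambiguous", "borderline", "unmatched", "expert_resolved", "rejected"
]
Method = Literal["absolute", "fuzzy_ngram", "dict_absolute", "dict_fuzzy", "expert"]

PHASE1 = "Phase 1: Drug Name Standardization"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one standardization attempt."""

    record_id: str
    status: Status
    canonical_name: str | None = None
    method: Method | None = None
    score: SimilarityScore | None = None
    candidates: tuple[CandidateMatch, ...] = ()
    stage: int = 0
    entry: NormalizedEntry | None = field(default=None, compare=False)


@dataclass(frozen=True)
class StandardizationConfig:
    """Thresholds and toggles for the Phase-1 stages.

    ``fuzzy_threshold`` is inclusive (score >= threshold matches);
    scores in ``[borderline_low, fuzzy_threshold)`` are held for review.
    """

    fuzzy_threshold: float = 0.90
    borderline_low: float = 0.85
    ngram_n: int = 2
    fuzzy_metric: Literal["jaccard_ngram", "levenshtein"] = "jaccard_ngram"
    enable_fuzzy: bool = True
    enable_dictionary: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.borderline_low <= self.fuzzy_threshold <= 1:
            raise ConfigurationError(
                "require 0 < borderline_low <= fuzzy_threshold <= 1, got "
                f"borderline_low={self.borderline_low}, "
                f"fuzzy_threshold={self.fuzzy_threshold}"
            )

    def metric(self) -> Callable[[str, str], SimilarityScore]:
        if self.fuzzy_metric == "levenshtein":
            return levenshtein_similarity
        n = self.ngram_n
        return lambda a, b: jaccard_ngram(a, b, n)


def _is_combination(norm: NormalizedEntry, components: list[str]) -> bool:
    # A combination arises from hyphen-splitting, not from several
    # free-standing tokens: splitting must have increased the count.
    return len(components) > len(norm.name_tokens) and len(components) >= 2


def _query_scopes(norm: NormalizedEntry) -> list[str]:
    """Candidate query strings in priority order: whole name, primary
    combination component, then every component."""
    components = split_combination(norm)
    scopes: list[str] = []
    if norm.name_text:
        scopes.append(norm.name_text)
    if _is_combination(norm, components):
        scopes.append(components[0])
    for comp in components:
        if comp not in scopes:
            scopes.append(comp)
    return scopes


def absolute_match(norm: NormalizedEntry, lexicon: dict[str, str]) -> MatchResult:
    """Exact (case/punctuation-normalized) lookup of the entry in the lexicon.

    ``lexicon`` maps normalized generic and trade names to their canonical
    generic.  Scope order: the whole rejoined name, then the primary
    combination component, then every component; within the component
    scope, hits on two or more distinct generics are ambiguous.
    """
    if not lexicon:
        raise ValidationError("lexicon must be non-empty")
    if not norm.name_text:
        return MatchResult(norm.record_id, "unmatched", stage=1, entry=norm)

    whole = lexicon.get(norm.name_text)
    if whole is not None:
        return MatchResult(
            norm.record_id, "matched", whole, "absolute",
            SimilarityScore(1.0, "jaccard_ngram"), stage=1, entry=norm,
        )

    components = split_combination(norm)
    if _is_combination(norm, components):
        primary = lexicon.get(components[0])
        if primary is not None:
            return MatchResult(
                norm.record_id, "matched", primary, "absolute",
                SimilarityScore(1.0, "jaccard_ngram"), stage=1, entry=norm,
            )

    hits = {comp: lexicon[comp] for comp in components if comp in lexicon}
    distinct = sorted(set(hits.values()))
    if len(distinct) == 1:
        return MatchResult(
            norm.record_id, "matched", distinct[0], "absolute",
            SimilarityScore(1.0, "jaccard_ngram"), stage=1, entry=norm,
        )
    if len(distinct) >= 2:
        candidates = tuple(
            CandidateMatch(name, SimilarityScore(1.0, "jaccard_ngram"), rank)
            for rank, name in enumerate(distinct, start=1)
        )
        return MatchResult(
            norm.record_id, "ambiguous", None, "absolute",
            candidates=candidates, stage=1, entry=norm,
        )
    return MatchResult(norm.record_id, "unmatched", stage=1, entry=norm)


def _fuzzy_against(
    norm: NormalizedEntry,
    keys: Sequence[str],
    canonical_of: Callable[[str], str],
    cfg: StandardizationConfig,
    method: Method,
    stage: int,
) -> MatchResult:
    """Shared fuzzy logic for the lexicon and dictionary fuzzy stages."""
    metric = cfg.metric()
    for query in _query_scopes(norm):
        scored = sorted(
            ((metric(query, k), k) for k in keys),
            key=lambda t: (-t[0].value, t[1]),
        )
        over = [
            CandidateMatch(k, s, rank)
            for rank, (s, k) in enumerate(scored, start=1)
            if s.value >= cfg.borderline_low
        ]
        if not over:
            continue
        top = over[0].score.value
        if top >= cfg.fuzzy_threshold:
            tied = [m for m in over if m.score.value == top]
            canonicals = sorted({canonical_of(m.candidate) for m in tied})
            if len(canonicals) == 1:
                return MatchResult(
                    norm.record_id, "matched", canonicals[0], method,
                    over[0].score, tuple(over), stage, entry=norm,
                )
            return MatchResult(
                norm.record_id, "ambiguous", None, method,
                over[0].score, tuple(over), stage, entry=norm,
            )
        # borderline band [borderline_low, threshold): held for review
        return MatchResult(
            norm.record_id, "borderline", None, method,
            over[0].score, tuple(over), stage, entry=norm,
        )
    return MatchResult(norm.record_id, "unmatched", stage=stage, entry=norm)


def fuzzy_match_stage(
    norm: NormalizedEntry, lexicon: dict[str, str], cfg: StandardizationConfig
) -> MatchResult:
    """Spelling-tolerant match of an absolute-unmatched entry against the lexicon."""
    if not lexicon:
        return MatchResult(norm.record_id, "unmatched", stage=2, entry=norm)
    keys = sorted(lexicon)
    return _fuzzy_against(norm, keys, lexicon.__getitem__, cfg, "fuzzy_ngram", 2)


def dictionary_match(
    norm: NormalizedEntry,
    dictionary: VariantDictionary,
    cfg: StandardizationConfig,
    mode: Literal["absolute", "fuzzy", "both"] = "both",
) -> MatchResult:
    """Resolve an entry through the expert-curated variant dictionary.

    Exact lookup of the normalized name and of each combination component
    first (method ``dict_absolute``); failing that, a fuzzy pass over the
    dictionary keys at the configured threshold (method ``dict_fuzzy``).
    """
    if mode in ("absolute", "both"):
        for query in _query_scopes(norm):
            canonical = dictionary.entries.get(query)
            if canonical is not None:
                return MatchResult(
                    norm.record_id, "matched", canonical, "dict_absolute",
                    SimilarityScore(1.0, "jaccard_ngram"), stage=3, entry=norm,
                )
        if mode == "absolute":
            return MatchResult(norm.record_id, "unmatched", stage=3, entry=norm)
    if not dictionary.entries:
        return MatchResult(norm.record_id, "unmatched", stage=4, entry=norm)
    return _fuzzy_against(
        norm, dictionary.keys(), dictionary.entries.__getitem__,
        cfg, "dict_fuzzy", 4,
    )


@dataclass
class CorpusStandardization:
    """Full Phase-1 outcome: per-record results, review queues, stage counts."""

    results: list[MatchResult]
    queues: dict[str, list[MatchResult]]
    counts: list[StageCounts]

    def by_id(self) -> dict[str, MatchResult]:
        return {r.record_id: r for r in self.results}


_STAGES: list[tuple[int, str]] = [
    (1, "1. Absolute Match"),
    (2, "2. Fuzzy Match"),
    (3, "3. Absolute Match Through Expert-Curated Dictionary"),
    (4, "4. Fuzzy Match Through Expert-Curated Dictionary"),
]


def standardize_corpus(
    entries: Sequence[NormalizedEntry],
    lexicon: dict[str, str],
    dictionary: VariantDictionary,
    cfg: StandardizationConfig | None = None,
    audit: AuditLog | None = None,
) -> CorpusStandardization:
    """Run the staged Phase-1 pipeline over a normalized, exclusion-filtered corpus.

    Each stage sees only the previous stage's unmatched entries; ambiguous
    and borderline results are frozen at first flagging.  Every entry ends
    in exactly one terminal state and the per-stage counts conserve:
    correct + flagged + unmatched = stage input.
    """
    cfg = cfg or StandardizationConfig()
    phase_total = len(entries)
    final: dict[str, MatchResult] = {}
    counts: list[StageCounts] = []
    pending = list(entries)

    for stage, label in _STAGES:
        if stage == 2 and not cfg.enable_fuzzy:
            continue
        if stage in (3, 4) and not cfg.enable_dictionary:
            continue
        still_unmatched: list[NormalizedEntry] = []
        n_in = len(pending)
        n_correct = n_flagged = 0
        for norm in pending:
            if stage == 1:
                res = absolute_match(norm, lexicon)
            elif stage == 2:
                res = fuzzy_match_stage(norm, lexicon, cfg)
            elif stage == 3:
                res = dictionary_match(norm, dictionary, cfg, mode="absolute")
            else:
                res = dictionary_match(norm, dictionary, cfg, mode="fuzzy")
            if res.status == "matched":
                n_correct += 1
                final[norm.record_id] = res
            elif res.status in ("ambiguous", "borderline"):
                n_flagged += 1
                final[norm.record_id] = res
            else:
                still_unmatched.append(norm)
            if audit is not None and res.status != "unmatched":
                audit.append(
                    norm.record_id, PHASE1, stage, "match",
                    before="unmatched", after=res.status,
                    score_pct=res.score.percent if res.score else None,
                )
        counts.append(
            StageCounts(
                PHASE1, label, n_correct, n_flagged, n_in - n_correct - n_flagged,
                n_in, phase_total,
            )
        )
        pending = still_unmatched

    for norm in pending:
        final[norm.record_id] = MatchResult(
            norm.record_id, "unmatched", stage=4, entry=norm
        )
        if audit is not None:
            audit.append(
                norm.record_id, PHASE1, 4, "exhausted",
                before="unmatched", after="unmatched",
            )

    results = [final[e.record_id] for e in entries]
    queues = {
        "ambiguous": [r for r in results if r.status == "ambiguous"],
        "borderline": [r for r in results if r.status == "borderline"],
        "unmatched": [r for r in results if r.status == "unmatched"],
    }
    return CorpusStandardization(results, queues, counts)


# ---------------------------------------------------------------------------
# Expert adjudication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpertDecision:
    record_id: str
    action: Literal["accept", "reject"]
    canonical_name: str = ""
    reviewer: str = ""
    date: str = ""


def load_decisions(path: str | Path) -> list[ExpertDecision]:
    """Read an adjudication file (record_id, action, canonical_name, reviewer, date)."""
    df = read_delimited(path)
    missing = [c for c in ("record_id", "action") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: decisions file missing column(s) {missing}")
    out = []
    for r in df.itertuples():
        if r.action not in ("accept", "reject"):
            raise ValidationError(
                f"decision for record {r.record_id}: unknown action {r.action!r}"
            )
        out.append(
            ExpertDecision(
                str(r.record_id), r.action,
                getattr(r, "canonical_name", ""),
                getattr(r, "reviewer", ""), getattr(r, "date", ""),
            )
        )
    return out


def apply_expert_decisions(
    standardization: CorpusStandardization,
    decisions: Sequence[ExpertDecision],
    dictionary: VariantDictionary,
    audit: AuditLog | None = None,
) -> CorpusStandardization:
    """Apply adjudicated decisions to the review queues (stage 5).

    Accepted entries become ``expert_resolved`` and their variant →
    canonical pair is appended to the reusable dictionary with provenance;
    rejected entries become terminal ``rejected`` and are excluded from
    Phase 2.  A decision naming a record that is not queued is a
    validation error.  Returns a new :class:`CorpusStandardization` with
    an appended stage-5 count row.
    """
    queued = {
        r.record_id: r
        for q in standardization.queues.values()
        for r in q
    }
    unknown = [d.record_id for d in decisions if d.record_id not in queued]
    if unknown:
        raise ValidationError(
            f"decisions reference records not in any review queue: {unknown}"
        )
    phase_total = (
        standardization.counts[0].phase_total if standardization.counts
        else len(standardization.results)
    )

    updated = standardization.by_id()
    n_resolved = 0
    for d in decisions:
        before = queued[d.record_id]
        if d.action == "accept":
            if not d.canonical_name:
                raise ValidationError(
                    f"accept decision for {d.record_id} lacks a canonical name"
                )
            after = replace(
                before, status="expert_resolved", canonical_name=d.canonical_name,
                method="expert", stage=5,
            )
            n_resolved += 1
            if before.entry is not None and before.entry.name_text:
                dictionary.add(
                    before.entry.name_text, d.canonical_name,
                    source="expert-adjudicated", date=d.date,
                )
        else:
            after = replace(before, status="rejected", method="expert", stage=5)
        updated[d.record_id] = after
        if audit is not None:
            audit.append(
                d.record_id, PHASE1, 5, d.action,
                before=before.status, after=after.status,
                actor=d.reviewer or "reviewer",
            )

    results = [updated[r.record_id] for r in standardization.results]
    n_in = len(queued)
    n_rejected = sum(
        1 for d in decisions if d.action == "reject"
    )
    counts = standardization.counts + [
        StageCounts(
            PHASE1, "5. Expert Review", n_resolved, 0,
            n_in - n_resolved, n_in, phase_total,
        )
    ]
    queues = {
        "ambiguous": [r for r in results if r.status == "ambiguous"],
        "borderline": [r for r in results if r.status == "borderline"],
        "unmatched": [r for r in results if r.status == "unmatched"],
    }
    return CorpusStandardization(results, queues, counts)


def results_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    """Results as a flat table (record_id, status, canonical, method, score, stage)."""
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "status": r.status,
                "canonical_name": r.canonical_name or "",
                "method": r.method or "",
                "score_pct": r.score.percent if r.score else "",
                "stage": r.stage,
            }
            for r in results
        ]
    )
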