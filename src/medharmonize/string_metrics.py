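"""Character-level similarity primitives used by the matching stages.

Two metrics drive the pipeline: character n-gram Jaccard similarity
(the spelling-tolerant matcher used during name standardization) and
normalized Levenshtein similarity (used when benchmarking names against
clinical-drug-form descriptions).  Both return scores in [0, 1] and are
compared to thresholds inclusively (a score exactly at the threshold
counts as a match).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

__all__ = [
    "SimilarityScore",
    "CandidateMatch",
    "jaccard_ngram",
    "levenshtein_distance",
    "levenshtein_similarity",
    "extract_best",
]

MetricName = Literal["jaccard_ngram", "levenshtein"]


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity value in [0, 1] tagged with the metric that produced it."""

    value: float
    metric: MetricName

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"similarity value out of range: {self.value}")

    @property
    def percent(self) -> float:
        """The score as a percentage rounded to one decimal (audit format)."""
        return round(self.value * 100.0, 1)


@dataclass(frozen=True)
class CandidateMatch:
    """One reference name scored against a query, with its rank (1 = best)."""

    candidate: str
    score: SimilarityScore
    rank: int


def _ngrams(s: str, n: int) -> frozenset[str]:
    return frozenset(s[i : i + n] for i in range(len(s) - n + 1))


def jaccard_ngram(a: str, b: str, n: int = 2) -> SimilarityScore:
    """Jaccard similarity between the sets of character ``n``-grams of two strings.

    N-grams are collected as a *set* (multiplicity is ignored).  If either
    string is shorter than ``n`` the metric degenerates and we fall back to
    exact equality (1.0 or 0.0).  Symmetric by construction.
    """
    if n < 1:
        raise ValueError(f"n-gram size must be >= 1, got {n}")
    if len(a) < n or len(b) < n:
        return SimilarityScore(1.0 if a == b else 0.0, "jaccard_ngram")
    ga, gb = _ngrams(a, n), _ngrams(b, n)
    union = ga | gb
    value = len(ga & gb) / len(union)
    return SimilarityScore(value, "jaccard_ngram")


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance by dynamic programming (two-row iteration)."""
    if a == b:
        return 0
    if len(a) < len(b):  # iterate over the shorter string's columns
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            curr[j] = min(
                prev[j] + 1,  # deletion
                curr[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != cb),  # substitution / copy
            )
        prev = curr
    return prev[-1]


def levenshtein_similarity(a: str, b: str) -> SimilarityScore:
    """Normalized Levenshtein similarity, 1 - d(a, b) / max(|a|, |b|).

    Two empty strings are defined to be identical (similarity 1.0).
    """
    if not a and not b:
        return SimilarityScore(1.0, "levenshtein")
    longest = max(len(a), len(b))
    return SimilarityScore(1.0 - levenshtein_distance(a, b) / longest, "levenshtein")


def extract_best(
    query: str,
    candidates: Sequence[str],
    metric: Callable[[str, str], SimilarityScore] = jaccard_ngram,
    threshold: float = 0.90,
) -> tuple[CandidateMatch | None, list[CandidateMatch]]:
    """Score ``query`` against every candidate and return the unique best hit.

    Returns ``(best, over_threshold)`` where ``over_threshold`` lists every
    candidate scoring at or above ``threshold`` in rank order.  ``best`` is
    the top-ranked candidate only when its score meets the threshold *and*
    it is strictly better than the runner-up: a tie at the top score is an
    ambiguity signal and yields ``best = None`` while both tied candidates
    appear in ``over_threshold``.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    scored = sorted(
        ((metric(query, c), c) for c in candidates),
        key=lambda t: (-t[0].value, t[1]),
    )
    ranked = [CandidateMatch(c, s, rank) for rank, (s, c) in enumerate(scored, start=1)]
    over = [m for m in ranked if m.score.value >= threshold]
    if not over:
        return None, []
    top = over[0]
    tied = [m for m in over if m.score.value == top.score.value]
    if len(tied) > 1:
        return None, over
    return top, over
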