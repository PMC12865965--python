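# Methods

This note documents the models, parameters and design decisions behind
`medharmonize`: what the pipeline assumes, what the synthetic test bed does
and does not emulate, and where the genuinely open choices were made.

## Normalization

All matching operates on a canonical text form: lowercase, ASCII
punctuation replaced by single spaces, whitespace collapsed. Two
punctuation characters survive in context because they carry meaning:

* a hyphen between two alphanumerics stays inside its token — between
  letters it marks a combination product ("lisinopril-hctz"), between
  digits a dose range ("20-12.5");
* a period between digits stays (decimal doses, "12.5").

Normalization is idempotent, and tokens joined by single spaces reconstruct
the normalized string exactly — invariants the property tests exercise.

Dose, unit and frequency tokens (pure numerics, "mg", "ml", "daily",
"bid", …) are *retained* in the token stream for the audit trail but
flagged, and the matchers never treat them as drug-name candidates. This
protects precision: a two-letter unit must not fuzzy-hit a short drug name.
Hyphen fragments shorter than 3 characters are re-joined to their neighbour
before matching ("co-codamol" → "cocodamol"), avoiding false combination
splits. Empty entries are flagged and routed to the unmatched queue, never
silently dropped: the stage accounting must conserve.

Exclusion filtering (OTC drugs, vitamins, supplements) matches the whole
normalized string, the dose-stripped name, or any single non-dose token
against the curated term list; exact+token is the default because the
narrower exact mode misses "vitamin d 1000 iu". Both modes are available.

## Similarity metrics and thresholds

* **n-gram Jaccard** (default n = 2, no boundary padding):
  `J(a,b) = |G(a)∩G(b)| / |G(a)∪G(b)|` over *sets* of character n-grams.
  Strings shorter than n fall back to exact equality. Bigrams are the
  smallest size that separates realistic misspelling pairs
  (e.g. "amitriptiline" / "amitriptyline" scores ≈ 0.71).
* **Levenshtein similarity**: `1 − d(a,b)/max(|a|,|b|)` with unit-cost DP
  edit distance; two empty strings are defined to have similarity 1.0.
  The DP is verified against a recursive definition (exhaustively over a
  small alphabet) and against the edlib library on random pairs.

Thresholds are inclusive (≥). The standardization fuzzy stage matches at
≥ 0.90; scores in the borderline band [0.85, 0.90) are held for review
rather than accepted or discarded. Class mapping fuzzy-matches drug-form
strings at ≥ 0.90 with Levenshtein similarity; for a name of length ≥ 10
this admits exactly one edit. Drug-form strings are pre-stripped of
dose-form words ("oral", "tablet", …) before scoring, since self-reported
names rarely carry them; this is configurable off.

A tie at the top score is never broken lexicographically: it is an
ambiguity signal and the entry goes to the review queue. More generally an
entry is ambiguous when it resolves to ≥ 2 *distinct* canonical generics —
a brand name co-occurring with its own generic is one drug, not two.
Combination products are the deliberate exception: a hyphen-joined token
whose components are distinct drugs is resolved to its primary (first)
component rather than flagged, because combination reporting is a naming
convention, not an ambiguity. Only free-standing co-occurrence of two drug
names in one field is ambiguous.

## Staged standardization

Stages run in fixed order — absolute → fuzzy → dictionary-absolute →
dictionary-fuzzy → expert queue — and each stage sees only the previous
stage's unmatched entries. Ambiguous and borderline results freeze at
first flagging; uncertainty never propagates into later automated stages.
Per-stage counts obey `correct + flagged + unmatched = stage input`, and
report percentages divide by the *phase* total, rounded half-up to one
decimal (this reproduces published-style figures such as 14,273/16,902 =
84.4% exactly; banker's rounding would not).

Expert decisions arrive as a delimited file (record, accept/reject,
canonical name, reviewer, date) and may only reference queued records.
Accepted variant→canonical pairs append to the reusable dictionary with
provenance, so re-running the same corpus strictly shrinks the queues —
a monotonicity property the tests enforce. The stage-accounting report
emits expert share both as a fraction of entries and of unique names,
labelled, since the two denominators give different figures.

## Class mapping and the exposure matrix

The classification map is persistent: once a name is assigned its class
(with method and score), later runs serve it from the map without
recomputation; the map is keyed by the queried name so brand-name entries
survive a save/load round trip. A name legitimately carrying several
classes yields one assignment per class and sets each class indicator.

The wide matrix is binary by construction: cell (participant-visit, class)
is 1 iff at least one medication of that class was reported. Column
granularity defaults to full four-level class numbers with optional
roll-up to level 2 or 3 via the prefix hierarchy; the preferred analysis
level is study-specific, so it is a parameter, not a constant. Subclass
consolidation is a declarative merge map (from → to class number) applied
before pivoting, with transitive chains flattened and cycles rejected.
Participant-visits with no eligible medication appear as all-zero rows only
when a visit roster is supplied — from medication rows alone, "no drugs"
and "no data" are indistinguishable. Unclassified or rejected records are
excluded from the matrix and listed in a side table.

Threshold calibration mirrors a banded expert-review design: labeled fuzzy
matches are sampled (seeded, up to 5 per band) from the similarity bands
[0.86, 0.90), [0.90, 0.95), [0.95, 1.00], and the recommended threshold is
the lowest band edge from which every band at or above meets the precision
target (default 0.9).

## The synthetic test bed

The generator stands in for data that cannot ship: real self-reported
entries and licensed vocabulary tables. It emulates the noise processes
that matter for matching, with defaults fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| entries | 1,000 (100 participants × 2 visits × 5 meds) | desk-scale corpus |
| misspelling rate | 0.17 | upper range reported for free-text EHR medication fields |
| max edits per misspelling | 1 | dominant real-world error mode |
| known-variant share of misspellings | 0.85 | misspellings are heavy-tailed: a few recurrent variants per drug dominate; the reusable adjudicated dictionary is precisely the artifact that accumulates them |
| brand-for-generic swap | 0.20 | common in self-report |
| dose/frequency suffix | 0.35 | "20 mg", "20-12.5 mg daily" |
| combination products | 0.05 | hyphen-joined, classified by primary ingredient |
| OTC/supplement distractors | 0.15 | removed by the exclusion filter |
| reference pairwise distance | ≥ 4 edits | enforced by rejection sampling |

Names are built from consonant-vowel syllables plus common drug-name
suffixes (-statin, -pril, -olol, …) so fuzzy matching is realistically hard;
uniformly random strings would be trivially separable. The ≥ 4-edit floor
(enforced across generics, trade names *and* the OTC vocabulary) makes the
headline precision claim provable rather than probabilistic: a one-edit
corruption is ≥ 3 edits from every wrong name, so no automated stage can
mis-assign it. Recurrent misspellings seed the variant dictionary (tagged
`seeded`); one-off typos do not, and land in the review queue — which is
the intended behaviour, not a failure. Every emitted entry has exactly one
ground-truth record, and all generation is deterministic under the seed.

What the generator does **not** emulate — hence what passing tests do not
show about real data: real vocabulary scale (dozens of names, not tens of
thousands), real names that genuinely collide ("hydroxyzine" /
"hydralazine" are 4 edits apart but real lexicons contain closer pairs),
truncated or multi-drug free text beyond simple combinations, non-English
entries, and dose/route semantics (carried through but never parsed).

## Evaluation protocol

Recovery metrics are scored in two scopes. Precision and recall are
reported for the *automated* stages only (matched status, before any
adjudication): precision = correct canonical among matched, recall =
correct matches among eligible (non-excluded) truths. Classification
accuracy and exposure-matrix cellwise agreement are scored on the full
four-phase run including the adjudication replay (queued records resolved
from ground truth), mirroring the complete workflow in which expert review
is a calibration step, not an optional extra. An independent brute-force
recount of the metrics is part of the test suite.

## Numerical and degenerate-input choices

* Percentages: decimal half-up rounding to one decimal, never float
  banker's rounding.
* Similarity of two empty strings: 1.0 (documented convention); empty vs
  non-empty: 0.0.
* Shallow class numbers (fewer than 4 groups) fill deeper levels with the
  deepest available prefix, so the wide matrix never has missing labels;
  the separator dialect (`08:12.06.04`, all-colon, all-period) is
  canonicalized on input so joins stay exact.
* Duplicate dictionary keys with conflicting canonicals are an error at
  load time, listing both values.
* Delimiters are sniffed from the header line only (tab vs comma) —
  free-text fields make whole-file dialect sniffing unsafe.
* Audit-log records carry wall-clock ISO-8601 timestamps and are the only
  artifact excluded from byte-identity replay checks; manifests record
  config, version, input checksums and counts, but no timestamps.

## Known limitations

Dose, route, frequency and timing are carried but never parsed; exposure
is binary per class per visit, not dose-weighted. Combination products
contribute only their primary ingredient's class, obscuring secondary
pharmacology. The expert step is modelled as an importable decision file —
the package automates everything around clinical judgment, not the
judgment itself. Reference content is synthetic or user-supplied; no
licensed vocabulary data is included.
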