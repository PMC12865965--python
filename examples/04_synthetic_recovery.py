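"""Full four-phase run on a seeded synthetic corpus, scored against ground truth.

Generates 1,000 messy entries (17% misspellings, brand swaps, dose
suffixes, combinations, OTC distractors) over a reference set whose names
are pairwise >= 4 edits apart, runs standardization, simulates the
adjudication step from ground truth, classifies, builds the exposure
matrix, and prints recovery metrics.
"""

from medharmonize import (
    GeneratorConfig,
    StandardizationConfig,
    VariantDictionary,
    apply_expert_decisions,
    classify_all,
    evaluate_recovery,
    filter_exclusions,
    generate_corpus,
    generate_world,
    normalize,
    standardize_corpus,
    to_long,
    to_wide,
    truth_long,
)
from medharmonize.standardizer import ExpertDecision

cfg = GeneratorConfig(seed=1)
world = generate_world(cfg)
entries, truth, _ = generate_corpus(cfg, world)
eligible, excluded = filter_exclusions(
    [normalize(e) for e in entries], world.exclusions
)
print(f"{len(entries)} raw entries -> {len(eligible)} eligible after removing "
      f"{len(excluded)} OTC/supplement rows")

dictionary = VariantDictionary(dict(world.dictionary.entries),
                               dict(world.dictionary.provenance))
out = standardize_corpus(eligible, world.refset.lexicon(), dictionary,
                         StandardizationConfig(fuzzy_threshold=0.90))
for c in out.counts:
    print(f"  {c.process_label}: {c.correct} correct, {c.ambiguous} flagged, "
          f"{c.unmatched} unmatched ({c.percentage}% of phase)")

automated = evaluate_recovery(out.results, truth)
print(f"automated precision = {automated['standardization_precision']:.3f}, "
      f"recall = {automated['standardization_recall']:.3f}")

# simulate the pharmacist/physician adjudication from ground truth
truth_by_id = {str(r.record_id): r for r in truth.itertuples()}
decisions = [
    ExpertDecision(r.record_id,
                   "accept" if truth_by_id[r.record_id].true_canonical
                   else "reject",
                   truth_by_id[r.record_id].true_canonical, "replay", "")
    for q in out.queues.values() for r in q
]
final = apply_expert_decisions(out, decisions, dictionary)

names = sorted({r.canonical_name for r in final.results if r.canonical_name})
classmap, unresolved, _ = classify_all(names, world.refset)
resolved = [r for r in final.results
            if r.status in ("matched", "expert_resolved")]
long_df, _ = to_long(resolved, classmap)
metrics = evaluate_recovery(
    final.results, truth, classmap,
    to_wide(long_df), to_wide(truth_long(truth)),
    matched_statuses=("matched", "expert_resolved"),
)
print(f"classification accuracy = {metrics['classification_accuracy']:.3f} "
      f"over {len(names)} unique names ({len(unresolved)} unresolved)")
print(f"exposure-matrix cellwise agreement = "
      f"{metrics['exposure_agreement']:.3f}")

print()
print("Precision stays at 1.0 because reference names are >= 4 edits apart:")
print("a one-edit typo can never sit closer to the wrong drug. Recall below")
print("1.0 before adjudication is exactly the queued one-off typos.")
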