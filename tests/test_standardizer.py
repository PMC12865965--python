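"""Phase-1 staged standardization: stages, queues, conservation, adjudication."""

import pytest

from medharmonize.audit_report import AuditLog
from medharmonize.exceptions import ConfigurationError, ValidationError
from medharmonize.reference_model import VariantDictionary
from medharmonize.standardizer import (
    ExpertDecision,
    StandardizationConfig,
    absolute_match,
    apply_expert_decisions,
    dictionary_match,
    fuzzy_match_stage,
    standardize_corpus,
)
from medharmonize.string_metrics import jaccard_ngram
from medharmonize.textnorm import RawMedicationEntry, filter_exclusions, normalize

LEXICON = {
    "atorvastatin": "atorvastatin",
    "metformin": "metformin",
    "lisinopril": "lisinopril",
    "hydrochlorothiazide": "hydrochlorothiazide",
    "lipitor": "atorvastatin",  # brand -> generic
}


def norm(text, rid="r1"):
    return normalize(RawMedicationEntry(rid, "p1", "v1", text))


class TestAbsoluteMatch:
    def test_token_hit_with_dose_suffix(self):
        res = absolute_match(norm("fluoxetine 20 mg"), {"fluoxetine": "fluoxetine"})
        assert res.status == "matched"
        assert res.canonical_name == "fluoxetine"
        assert res.method == "absolute"

    def test_two_free_standing_generics_are_ambiguous(self):
        res = absolute_match(norm("atorvastatin metformin"), LEXICON)
        assert res.status == "ambiguous"
        assert {c.candidate for c in res.candidates} == {
            "atorvastatin", "metformin",
        }

    def test_brand_plus_its_generic_is_not_ambiguous(self):
        res = absolute_match(norm("lipitor atorvastatin"), LEXICON)
        assert res.status == "matched"
        assert res.canonical_name == "atorvastatin"

    def test_combination_resolves_to_primary_ingredient(self):
        res = absolute_match(norm("lisinopril-hydrochlorothiazide"), LEXICON)
        assert res.status == "matched"
        assert res.canonical_name == "lisinopril"

    def test_unknown_token_unmatched(self):
        assert absolute_match(norm("xyzzy"), LEXICON).status == "unmatched"

    def test_case_insensitive(self):
        res = absolute_match(norm("LIPITOR"), LEXICON)
        assert res.status == "matched" and res.canonical_name == "atorvastatin"


class TestFuzzyStage:
    def test_misspelling_matches_when_threshold_below_oracle_score(self):
        score = jaccard_ngram("amitriptiline", "amitriptyline", 2).value
        cfg = StandardizationConfig(
            fuzzy_threshold=round(score - 0.01, 3),
            borderline_low=round(score - 0.02, 3),
        )
        res = fuzzy_match_stage(
            norm("amitriptiline"), {"amitriptyline": "amitriptyline"}, cfg
        )
        assert res.status == "matched"
        assert res.canonical_name == "amitriptyline"
        assert res.method == "fuzzy_ngram"
        assert res.score.value == pytest.approx(score)

    def test_score_in_band_is_borderline(self):
        # mid-string substitution on a 30-char name: 27/31 bigrams shared
        a = "abcdefghijklmnopqrstuvwxyzbdfh"
        b = a[:13] + "0" + a[14:]
        score = jaccard_ngram(a, b, 2).value
        assert 0.85 <= score < 0.90
        cfg = StandardizationConfig()
        res = fuzzy_match_stage(norm(a), {b: b}, cfg)
        assert res.status == "borderline"
        assert res.candidates  # held with its candidate list for review

    def test_empty_lexicon_is_unmatched(self):
        res = fuzzy_match_stage(norm("anything"), {}, StandardizationConfig())
        assert res.status == "unmatched"

    def test_invalid_band_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            StandardizationConfig(fuzzy_threshold=0.8, borderline_low=0.9)


class TestDictionaryMatch:
    def test_exact_variant_lookup(self):
        d = VariantDictionary()
        d.add("lipator", "atorvastatin")
        res = dictionary_match(norm("lipator"), d, StandardizationConfig())
        assert res.status == "matched"
        assert res.canonical_name == "atorvastatin"
        assert res.method == "dict_absolute"

    def test_fuzzy_variant_lookup_iff_score_clears_threshold(self):
        d = VariantDictionary()
        d.add("lipator", "atorvastatin")
        score = jaccard_ngram("lipatorr", "lipator", 2).value
        cfg = StandardizationConfig(
            fuzzy_threshold=round(score - 0.01, 3),
            borderline_low=round(score - 0.01, 3),
        )
        res = dictionary_match(norm("lipatorr"), d, cfg)
        assert res.status == "matched" and res.method == "dict_fuzzy"
        high = StandardizationConfig(fuzzy_threshold=0.99, borderline_low=0.99)
        assert dictionary_match(norm("lipatorr"), d, high).status == "unmatched"

    def test_empty_dictionary_unmatched(self):
        res = dictionary_match(
            norm("anything"), VariantDictionary(), StandardizationConfig()
        )
        assert res.status == "unmatched"


class TestStandardizeCorpus:
    def test_all_clean_corpus_fully_matched_at_stage_one(self):
        entries = [norm(name, f"r{i}") for i, name in enumerate(LEXICON)]
        out = standardize_corpus(entries, LEXICON, VariantDictionary())
        assert all(r.status == "matched" and r.stage == 1 for r in out.results)
        assert out.counts[0].correct == len(entries)

    def test_garbage_corpus_all_unmatched(self):
        entries = [norm(t, f"r{i}") for i, t in enumerate(["qq", "zz xx", "wwww"])]
        out = standardize_corpus(entries, LEXICON, VariantDictionary())
        assert all(r.status == "unmatched" for r in out.results)
        assert not out.queues["ambiguous"] and not out.queues["borderline"]
        assert len(out.queues["unmatched"]) == 3

    def test_stage_conservation_on_synthetic_corpus(self, world, corpus,
                                                    fresh_dictionary):
        from medharmonize.textnorm import normalize as norm_entry

        entries, truth, _ = corpus
        normalized = [norm_entry(e) for e in entries]
        eligible, _ = filter_exclusions(normalized, world.exclusions)
        out = standardize_corpus(
            eligible, world.refset.lexicon(), fresh_dictionary
        )
        # every stage conserves: correct + flagged + unmatched = stage input
        for count in out.counts:
            assert count.correct + count.ambiguous + count.unmatched == count.total
        # stages chain: next stage's input = previous stage's unmatched
        for prev, nxt in zip(out.counts, out.counts[1:]):
            assert nxt.total == prev.unmatched
        # every entry ends in exactly one terminal state
        assert len(out.results) == len(eligible)
        statuses = {r.status for r in out.results}
        assert statuses <= {"matched", "ambiguous", "borderline", "unmatched"}

    def test_determinism_byte_identical(self, world, corpus, fresh_dictionary):
        from medharmonize.standardizer import results_frame
        from medharmonize.textnorm import normalize as norm_entry

        entries, _, _ = corpus
        normalized = [norm_entry(e) for e in entries[:200]]
        eligible, _ = filter_exclusions(normalized, world.exclusions)
        lex = world.refset.lexicon()
        a = standardize_corpus(eligible, lex, fresh_dictionary)
        b = standardize_corpus(eligible, lex, fresh_dictionary)
        assert results_frame(a.results).to_csv() == results_frame(b.results).to_csv()

    def test_threshold_monotonicity(self, world, corpus, fresh_dictionary):
        from medharmonize.textnorm import normalize as norm_entry

        entries, _, _ = corpus
        normalized = [norm_entry(e) for e in entries[:400]]
        eligible, _ = filter_exclusions(normalized, world.exclusions)
        lex = world.refset.lexicon()
        matched_counts = []
        for thr in (0.80, 0.85, 0.90, 0.95, 1.00):
            cfg = StandardizationConfig(
                fuzzy_threshold=thr, borderline_low=min(0.85, thr)
            )
            out = standardize_corpus(eligible, lex, fresh_dictionary, cfg)
            matched_counts.append(
                sum(1 for r in out.results if r.status == "matched")
            )
        assert matched_counts == sorted(matched_counts, reverse=True)


class TestExpertDecisions:
    def _queued_corpus(self, world, corpus, dictionary):
        from medharmonize.textnorm import normalize as norm_entry

        entries, truth, _ = corpus
        normalized = [norm_entry(e) for e in entries]
        eligible, _ = filter_exclusions(normalized, world.exclusions)
        out = standardize_corpus(eligible, world.refset.lexicon(), dictionary)
        truth_by_id = {str(r.record_id): r for r in truth.itertuples()}
        return eligible, out, truth_by_id

    def test_accept_resolves_and_grows_dictionary(self, world, corpus,
                                                  fresh_dictionary):
        eligible, out, truth_by_id = self._queued_corpus(
            world, corpus, fresh_dictionary
        )
        queued = [r for q in out.queues.values() for r in q]
        assert queued, "synthetic corpus should leave something for review"
        n_before = len(fresh_dictionary)
        decisions = [
            ExpertDecision(
                r.record_id, "accept",
                truth_by_id[r.record_id].true_canonical, "rev1", "2025-06-01",
            )
            for r in queued
            if truth_by_id[r.record_id].true_canonical
        ]
        audit = AuditLog()
        out2 = apply_expert_decisions(out, decisions, fresh_dictionary, audit)
        resolved = [r for r in out2.results if r.status == "expert_resolved"]
        assert len(resolved) == len(decisions)
        assert all(r.stage == 5 and r.method == "expert" for r in resolved)
        assert len(fresh_dictionary) > n_before
        assert len(audit.records) == len(decisions)

    def test_replay_with_grown_dictionary_shrinks_queues(self, world, corpus,
                                                         fresh_dictionary):
        eligible, out, truth_by_id = self._queued_corpus(
            world, corpus, fresh_dictionary
        )
        n_queued_before = sum(len(q) for q in out.queues.values())
        decisions = [
            ExpertDecision(
                r.record_id, "accept",
                truth_by_id[r.record_id].true_canonical, "rev1", "",
            )
            for q in out.queues.values()
            for r in q
            if truth_by_id[r.record_id].true_canonical
        ]
        apply_expert_decisions(out, decisions, fresh_dictionary)
        replay = standardize_corpus(
            eligible, world.refset.lexicon(), fresh_dictionary
        )
        n_queued_after = sum(len(q) for q in replay.queues.values())
        assert n_queued_after < n_queued_before
        # dictionary growth never un-matches a previously matched entry
        before = {r.record_id for r in out.results if r.status == "matched"}
        after = {r.record_id for r in replay.results if r.status == "matched"}
        assert before <= after

    def test_reject_is_terminal(self, world, corpus, fresh_dictionary):
        _eligible, out, _ = self._queued_corpus(world, corpus, fresh_dictionary)
        target = out.queues["unmatched"][0]
        out2 = apply_expert_decisions(
            out, [ExpertDecision(target.record_id, "reject", "", "rev1", "")],
            fresh_dictionary,
        )
        assert out2.by_id()[target.record_id].status == "rejected"

    def test_decision_for_unqueued_record_rejected(self, world, corpus,
                                                   fresh_dictionary):
        _eligible, out, _ = self._queued_corpus(world, corpus, fresh_dictionary)
        matched = next(r for r in out.results if r.status == "matched")
        with pytest.raises(ValidationError):
            apply_expert_decisions(
                out,
                [ExpertDecision(matched.record_id, "accept", "x", "rev1", "")],
                fresh_dictionary,
            )
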