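"""Generator guarantees: determinism, separability, noise rates, recovery scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medharmonize.string_metrics import levenshtein_distance
from medharmonize.synthetic import (
    GeneratorConfig,
    corrupt_name,
    evaluate_recovery,
    generate_corpus,
    generate_world,
    truth_long,
)
from medharmonize.exceptions import ValidationError
from medharmonize.reference_model import derive_class_levels
from medharmonize.standardizer import MatchResult


class TestGenerateReference:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(seed=5, n_generics=15)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert w1.generics == w2.generics
        assert w1.dictionary.entries == w2.dictionary.entries
        pd.testing.assert_frame_equal(w1.refset.classes, w2.refset.classes)

    def test_pairwise_distance_floor(self, world):
        """Every generated name pair (generic+trade) is >= 4 edits apart."""
        names = list(world.canonical_of)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert levenshtein_distance(a, b) >= 4, (a, b)

    def test_every_class_num_parses(self, world):
        for num in world.refset.classes["AHFSClassNum"]:
            l2, l3, l4 = derive_class_levels(num)
            assert l4 == num

    def test_reference_passes_integrity_checks(self, tmp_path, world):
        from medharmonize.reference_model import load_reference_set

        paths = {}
        for table in ("generics", "tradenames", "scdf", "classes",
                      "classes_extended"):
            path = tmp_path / f"{table}.csv"
            getattr(world.refset, table).to_csv(path, index=False)
            paths[table] = path
        refset = load_reference_set(paths)
        assert refset.counts() == world.refset.counts()


class TestCorruptName:
    def test_zero_rates_identity(self):
        cfg = GeneratorConfig(
            misspelling_rate=0, dose_suffix_rate=0, case_noise_rate=0, seed=0
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            text, ops = corrupt_name("atorvastatin", cfg, rng)
            assert text == "atorvastatin" and ops == []

    def test_single_edit_stays_within_one_edit(self):
        cfg = GeneratorConfig(
            misspelling_rate=1.0, known_variant_rate=0.0,
            dose_suffix_rate=0, case_noise_rate=0, max_edits_per_name=1,
        )
        rng = np.random.default_rng(2)
        for _ in range(200):
            text, ops = corrupt_name("cefadopril", cfg, rng)
            assert levenshtein_distance(text, "cefadopril") == 1
            assert ops == ["edit:fresh"]

    def test_known_variants_drawn_from_pool(self):
        cfg = GeneratorConfig(
            misspelling_rate=1.0, known_variant_rate=1.0,
            dose_suffix_rate=0, case_noise_rate=0,
        )
        pool = ["cefadoprul", "cefadoprit"]
        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(50):
            text, ops = corrupt_name("cefadopril", cfg, rng, pool)
            assert text in pool and ops == ["edit:known"]
            seen.add(text)
        assert seen == set(pool)


class TestGenerateCorpus:
    def test_byte_identical_under_seed(self):
        cfg = GeneratorConfig(seed=42, n_participants=20)
        e1, t1, m1 = generate_corpus(cfg)
        e2, t2, m2 = generate_corpus(cfg)
        assert e1 == e2
        pd.testing.assert_frame_equal(t1, t2)
        assert m1 == m2

    def test_ground_truth_completeness(self, corpus):
        entries, truth, _ = corpus
        assert len(entries) == len(truth)
        assert truth["record_id"].is_unique

    def test_otc_rate_within_binomial_bounds(self, corpus):
        _entries, truth, _ = corpus
        n = len(truth)
        k = int(truth["excluded"].sum())
        lo, hi = stats.binom.interval(0.99, n, 0.15)
        assert lo <= k <= hi

    def test_misspelling_rate_within_binomial_bounds(self, corpus):
        _entries, truth, _ = corpus
        eligible = truth[~truth["excluded"]]
        # combinations are rendered clean; edits apply to the remainder
        can_misspell = eligible[
            ~eligible["corruption"].str.contains("combination")
        ]
        k = can_misspell["corruption"].str.contains("edit:").sum()
        lo, hi = stats.binom.interval(0.99, len(can_misspell), 0.17)
        assert lo <= k <= hi

    def test_all_rates_zero_gives_clean_corpus(self):
        from medharmonize.standardizer import standardize_corpus
        from medharmonize.reference_model import VariantDictionary
        from medharmonize.textnorm import normalize

        cfg = GeneratorConfig(
            seed=3, n_participants=20, misspelling_rate=0, brand_swap_rate=0,
            dose_suffix_rate=0, combination_rate=0, otc_distractor_rate=0,
            case_noise_rate=0,
        )
        world = generate_world(cfg)
        entries, truth, _ = generate_corpus(cfg, world)
        assert not truth["excluded"].any()
        out = standardize_corpus(
            [normalize(e) for e in entries],
            world.refset.lexicon(), VariantDictionary(),
        )
        assert all(r.status == "matched" and r.stage == 1 for r in out.results)


class TestEvaluateRecovery:
    def _perfect_results(self, truth):
        out = []
        for r in truth.itertuples():
            if r.excluded:
                continue
            out.append(
                MatchResult(str(r.record_id), "matched", r.true_canonical)
            )
        return out

    def test_perfect_pipeline_scores_one(self, corpus):
        _entries, truth, _ = corpus
        m = evaluate_recovery(self._perfect_results(truth), truth)
        assert m["standardization_precision"] == 1.0
        assert m["standardization_recall"] == 1.0

    def test_exact_only_matching_keeps_precision_one(self, world, corpus):
        """Threshold 1.0 (exact-only): recall drops, precision stays 1.0."""
        from medharmonize.reference_model import VariantDictionary
        from medharmonize.standardizer import (
            StandardizationConfig, standardize_corpus,
        )
        from medharmonize.textnorm import filter_exclusions, normalize

        entries, truth, _ = corpus
        eligible, _ = filter_exclusions(
            [normalize(e) for e in entries], world.exclusions
        )
        cfg = StandardizationConfig(fuzzy_threshold=1.0, borderline_low=1.0)
        out = standardize_corpus(
            eligible, world.refset.lexicon(), VariantDictionary(), cfg
        )
        m = evaluate_recovery(out.results, truth)
        assert m["standardization_precision"] == 1.0
        assert m["standardization_recall"] < 1.0

    def test_id_mismatch_rejected(self, corpus):
        _entries, truth, _ = corpus
        with pytest.raises(ValidationError):
            evaluate_recovery(
                [MatchResult("NOT-AN-ID", "matched", "x")], truth
            )

    def test_metrics_agree_with_independent_recount(self, world, corpus,
                                                    fresh_dictionary):
        """Recompute precision/recall by brute force over the result list."""
        from medharmonize.standardizer import standardize_corpus
        from medharmonize.textnorm import filter_exclusions, normalize

        entries, truth, _ = corpus
        eligible, _ = filter_exclusions(
            [normalize(e) for e in entries], world.exclusions
        )
        out = standardize_corpus(
            eligible, world.refset.lexicon(), fresh_dictionary
        )
        m = evaluate_recovery(out.results, truth)
        tmap = dict(zip(truth["record_id"].astype(str),
                        truth["true_canonical"]))
        matched = [r for r in out.results if r.status == "matched"]
        n_correct = sum(1 for r in matched if tmap[r.record_id] ==
                        r.canonical_name)
        assert m["standardization_precision"] == n_correct / len(matched)
        assert m["standardization_recall"] == pytest.approx(
            n_correct / (~truth["excluded"]).sum()
        )

    def test_truth_matrix_agreement_against_itself(self, corpus):
        _entries, truth, _ = corpus
        from medharmonize.exposure import to_wide

        tm = to_wide(truth_long(truth))
        m = evaluate_recovery(
            self._perfect_results(truth), truth,
            matrix=tm, truth_matrix=tm,
        )
        assert m["exposure_agreement"] == 1.0
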