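"""Synthetic reference tables and messy medication corpora with ground truth.

Real self-reported medication data (and the licensed vocabularies it maps
to) cannot ship with the package, so this module builds a miniature world
with the same statistical character and full ground-truth labels:

* pronounceable generic names built from consonant-vowel syllables plus
  common drug-name suffixes (-statin, -pril, -olol...), with a guaranteed
  minimum pairwise edit distance (rejection sampling) so that recovery
  claims are provable rather than probabilistic;
* brand (trade) names, a four-level therapeutic-class grid, and
  clinical-drug-form strings of the form "<generic> oral tablet";
* a corpus generator that corrupts entries the way participants do:
  random case, misspellings (about 17% of free-text entries by default),
  brand-for-generic swaps, dose/frequency suffixes, hyphenated
  combination products, and OTC/supplement distractors;
* a seeded variant dictionary holding each name's *recurrent* misspellings
  (misspellings in free text are heavy-tailed: a handful of variants per
  drug account for most occurrences — exactly what an adjudicated,
  reusable dictionary captures across waves of data);
* recovery metrics comparing pipeline output against the ground truth.

Every operation is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .class_mapper import ClassificationMap
from .exceptions import MedHarmonizeError, ValidationError
from .reference_model import (
    AHFSReferenceSet,
    ExclusionList,
    VariantDictionary,
    derive_class_levels,
)
from .standardizer import MatchResult
from .string_metrics import levenshtein_distance
from .textnorm import RawMedicationEntry

__all__ = [
    "GeneratorConfig",
    "SyntheticWorld",
    "GenerationError",
    "generate_world",
    "generate_reference",
    "corrupt_name",
    "generate_corpus",
    "truth_long",
    "evaluate_recovery",
]


class GenerationError(MedHarmonizeError):
    """The name generator cannot satisfy its separation constraint."""


# Default OTC / vitamin / supplement distractors (normalized spellings).
OTC_TERMS: tuple[str, ...] = (
    "vitamin d", "vitamin c", "vitamin b12", "fish oil", "multivitamin",
    "calcium", "melatonin", "aspirin", "ibuprofen", "acetaminophen",
    "zinc", "magnesium", "glucosamine", "coq10", "folic acid",
)

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_GENERIC_SUFFIXES = (
    "statin", "pril", "olol", "oxetine", "azole", "sartan", "micin",
    "dipine", "zepam", "formin",
)
_TRADE_SUFFIXES = ("ex", "or", "ix", "an", "il", "ax")
_DOSES = ("10", "20", "25", "50", "100", "20-12.5", "12.5", "5")
_FREQ = ("daily", "twice daily", "prn", "nightly")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Rates are per *entry* (not per character).  ``misspelling_rate``
    reflects reported misspelling frequencies of up to ~17% in free-text
    medication fields; ``known_variant_rate`` is the share of misspellings
    that recur (and are therefore in the seeded variant dictionary) rather
    than being one-off typos.
    """

    n_participants: int = 100
    visits_per_participant: int = 2
    meds_per_visit: int = 5
    n_generics: int = 40
    n_trade_per_generic: int = 1
    n_classes: int = 12
    misspelling_rate: float = 0.17
    brand_swap_rate: float = 0.20
    dose_suffix_rate: float = 0.35
    combination_rate: float = 0.05
    otc_distractor_rate: float = 0.15
    case_noise_rate: float = 0.30
    known_variant_rate: float = 0.85
    n_known_variants: int = 3
    max_edits_per_name: int = 1
    min_pairwise_distance: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "misspelling_rate": self.misspelling_rate,
            "brand_swap_rate": self.brand_swap_rate,
            "dose_suffix_rate": self.dose_suffix_rate,
            "combination_rate": self.combination_rate,
            "otc_distractor_rate": self.otc_distractor_rate,
            "case_noise_rate": self.case_noise_rate,
            "known_variant_rate": self.known_variant_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")

    @property
    def n_entries(self) -> int:
        return self.n_participants * self.visits_per_participant * self.meds_per_visit


@dataclass
class SyntheticWorld:
    """Everything the generator knows: reference tables plus ground-truth maps."""

    config: GeneratorConfig
    refset: AHFSReferenceSet
    exclusions: ExclusionList
    dictionary: VariantDictionary
    generics: list[str]
    trade_of: dict[str, list[str]]
    class_of: dict[str, str]  # generic -> level-4 class number
    variant_pools: dict[str, list[str]]  # surface name -> recurrent misspellings
    canonical_of: dict[str, str]  # surface name (generic or trade) -> generic


def _syllable_name(rng: np.random.Generator, suffixes: Sequence[str]) -> str:
    n_syll = int(rng.integers(2, 4))
    core = "".join(
        _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
        + _VOWELS[int(rng.integers(len(_VOWELS)))]
        for _ in range(n_syll)
    )
    return core + suffixes[int(rng.integers(len(suffixes)))]


def _single_edit(rng: np.random.Generator, name: str) -> str:
    """One random insertion, deletion or substitution (letters only)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    while True:
        op = ("sub", "ins", "del")[int(rng.integers(3))]
        pos = int(rng.integers(len(name)))
        if op == "sub":
            c = letters[int(rng.integers(26))]
            out = name[:pos] + c + name[pos + 1:]
        elif op == "ins":
            c = letters[int(rng.integers(26))]
            out = name[:pos] + c + name[pos:]
        else:
            if len(name) <= 2:
                continue
            out = name[:pos] + name[pos + 1:]
        if out != name:
            return out


def _class_grid(rng: np.random.Generator, n_classes: int) -> list[str]:
    """Distinct four-group class numbers over a small hierarchy grid."""
    level1 = ["04", "08", "12", "24", "28", "40", "52", "68", "86", "92"]
    nums: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(nums) < n_classes:
        attempts += 1
        if attempts > 10000:  # pragma: no cover
            raise GenerationError("cannot build enough distinct class numbers")
        g1 = level1[int(rng.integers(len(level1)))]
        g2 = f"{int(rng.integers(1, 5)) * 4:02d}"
        g3 = f"{int(rng.integers(1, 4)) * 4:02d}"
        g4 = f"{int(rng.integers(1, 4)) * 4:02d}"
        num = f"{g1}:{g2}.{g3}.{g4}"
        if num not in seen:
            seen.add(num)
            nums.append(num)
    return nums


def generate_world(cfg: GeneratorConfig) -> SyntheticWorld:
    """Deterministically build the synthetic reference world for ``cfg``."""
    rng = np.random.default_rng(cfg.seed)

    class_nums = _class_grid(rng, cfg.n_classes)
    classes = pd.DataFrame(
        {
            "AHFSClassID": [f"C{i:03d}" for i in range(len(class_nums))],
            "AHFSClassNum": class_nums,
            "AHFSClassText": [f"Synthetic Agents {num}" for num in class_nums],
        }
    )
    ext_rows = []
    for num in class_nums:
        l2, l3, l4 = derive_class_levels(num)
        ext_rows.append(
            {
                "AHFSClassNum": num,
                "AHFSClassText_2": f"Level2 {l2}",
                "AHFSClassText_3": f"Level3 {l3}",
                "AHFSClassText_4": f"Level4 {l4}",
            }
        )
    classes_extended = pd.DataFrame(ext_rows)

    # Generic + trade names under the minimum-distance constraint (the OTC
    # vocabulary counts too: a corrupted prescription name must never
    # collide with a distractor).
    accepted: list[str] = [t.replace(" ", "") for t in OTC_TERMS]
    generics: list[str] = []
    trade_of: dict[str, list[str]] = {}
    max_attempts = 2000 * max(cfg.n_generics, 1)
    attempts = 0

    def admissible(candidate: str) -> bool:
        return all(
            levenshtein_distance(candidate, other) >= cfg.min_pairwise_distance
            for other in accepted
        )

    while len(generics) < cfg.n_generics:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"cannot place {cfg.n_generics} generics with pairwise "
                f"distance >= {cfg.min_pairwise_distance}; lower n_generics "
                "or the distance constraint"
            )
        cand = _syllable_name(rng, _GENERIC_SUFFIXES)
        if admissible(cand):
            generics.append(cand)
            accepted.append(cand)

    for g in generics:
        brands: list[str] = []
        while len(brands) < cfg.n_trade_per_generic:
            attempts += 1
            if attempts > max_attempts:
                raise GenerationError(
                    "cannot place trade names under the distance constraint"
                )
            cand = _syllable_name(rng, _TRADE_SUFFIXES)
            if admissible(cand):
                brands.append(cand)
                accepted.append(cand)
        trade_of[g] = brands

    class_of = {
        g: class_nums[int(rng.integers(len(class_nums)))] for g in generics
    }
    num_to_id = dict(zip(classes["AHFSClassNum"], classes["AHFSClassID"]))

    generics_df = pd.DataFrame(
        {
            "UN": [f"G{i:04d}" for i in range(len(generics))],
            "GenDrugName": generics,
            "AHFSClassID": [num_to_id[class_of[g]] for g in generics],
        }
    )
    trade_rows = []
    i = 0
    for g in generics:
        for b in trade_of[g]:
            trade_rows.append({"UN": f"T{i:04d}", "Tradename": b, "GenDrugName": g})
            i += 1
    tradenames_df = pd.DataFrame(trade_rows, columns=["UN", "Tradename", "GenDrugName"])

    scdf_df = pd.DataFrame(
        {
            "SCDF_STR": [f"{g} oral tablet" for g in generics],
            "SCDF_CUI": [f"CUI{i:05d}" for i in range(len(generics))],
            "AHFSClassNum": [class_of[g] for g in generics],
        }
    )

    refset = AHFSReferenceSet(
        generics=generics_df,
        tradenames=tradenames_df,
        scdf=scdf_df,
        classes=classes,
        classes_extended=classes_extended,
    )
    exclusions = ExclusionList.from_terms(OTC_TERMS)

    # Recurrent-misspelling pools + the seeded dictionary built from them.
    canonical_of: dict[str, str] = {g: g for g in generics}
    for g, brands in trade_of.items():
        for b in brands:
            canonical_of[b] = g
    dictionary = VariantDictionary()
    variant_pools: dict[str, list[str]] = {}
    for surface in sorted(canonical_of):
        pool: list[str] = []
        while len(pool) < cfg.n_known_variants:
            var = _single_edit(rng, surface)
            if var not in pool and var not in canonical_of:
                pool.append(var)
        variant_pools[surface] = pool
        for var in pool:
            dictionary.add(var, canonical_of[surface], source="seeded")

    return SyntheticWorld(
        config=cfg,
        refset=refset,
        exclusions=exclusions,
        dictionary=dictionary,
        generics=generics,
        trade_of=trade_of,
        class_of=class_of,
        variant_pools=variant_pools,
        canonical_of=canonical_of,
    )


def generate_reference(
    cfg: GeneratorConfig,
) -> tuple[AHFSReferenceSet, ExclusionList, VariantDictionary]:
    """The reference tables, exclusion list and seeded dictionary for ``cfg``."""
    world = generate_world(cfg)
    return world.refset, world.exclusions, world.dictionary


def _random_case(rng: np.random.Generator, text: str) -> str:
    style = int(rng.integers(3))
    if style == 0:
        return text.capitalize()
    if style == 1:
        return text.upper()
    return "".join(
        c.upper() if rng.random() < 0.3 else c for c in text
    )


def corrupt_name(
    name: str, cfg: GeneratorConfig, rng: np.random.Generator,
    variant_pool: Sequence[str] = (),
) -> tuple[str, list[str]]:
    """Apply the configured noise to one surface name.

    Returns the corrupted text and the list of corruption tags applied
    (``edit:known``, ``edit:fresh``, ``case``, ``dose_suffix``).  With all
    rates at zero the name passes through unchanged.
    """
    text = name
    ops: list[str] = []
    if rng.random() < cfg.misspelling_rate and cfg.max_edits_per_name > 0:
        if variant_pool and rng.random() < cfg.known_variant_rate:
            text = variant_pool[int(rng.integers(len(variant_pool)))]
            ops.append("edit:known")
        else:
            n_edits = int(rng.integers(1, cfg.max_edits_per_name + 1))
            for _ in range(n_edits):
                text = _single_edit(rng, text)
            ops.append("edit:fresh")
    if rng.random() < cfg.dose_suffix_rate:
        dose = _DOSES[int(rng.integers(len(_DOSES)))]
        suffix = f"{dose} mg"
        if rng.random() < 0.3:
            suffix += " " + _FREQ[int(rng.integers(len(_FREQ)))]
        text = f"{text} {suffix}"
        ops.append("dose_suffix")
    if rng.random() < cfg.case_noise_rate:
        text = _random_case(rng, text)
        ops.append("case")
    return text, ops


TRUTH_COLUMNS = [
    "record_id", "participant_id", "visit_id", "raw_text", "excluded",
    "true_canonical", "true_class_num", "corruption",
]


def generate_corpus(
    cfg: GeneratorConfig, world: SyntheticWorld | None = None
) -> tuple[list[RawMedicationEntry], pd.DataFrame, dict]:
    """Raw entries with participant-visit structure, ground truth, and a manifest.

    Each visit draws ``meds_per_visit`` records; a record is an OTC
    distractor with probability ``otc_distractor_rate``, else a
    prescription drug rendered as generic or brand, possibly misspelled,
    possibly a hyphenated combination, with optional dose suffix and case
    noise.  Byte-identical under a fixed seed.
    """
    world = world or generate_world(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    otc = sorted(world.exclusions.terms)

    entries: list[RawMedicationEntry] = []
    truth_rows: list[dict] = []
    i = 0
    for p in range(cfg.n_participants):
        pid = f"P{p:04d}"
        for v in range(cfg.visits_per_participant):
            vid = f"V{v + 1}"
            for _ in range(cfg.meds_per_visit):
                rid = f"R{i:05d}"
                i += 1
                if rng.random() < cfg.otc_distractor_rate:
                    term = otc[int(rng.integers(len(otc)))]
                    text = term
                    ops = []
                    if rng.random() < cfg.case_noise_rate:
                        text = _random_case(rng, text)
                        ops.append("case")
                    entries.append(RawMedicationEntry(rid, pid, vid, text))
                    truth_rows.append(
                        {
                            "record_id": rid, "participant_id": pid,
                            "visit_id": vid, "raw_text": text,
                            "excluded": True, "true_canonical": "",
                            "true_class_num": "",
                            "corruption": "|".join(["otc"] + ops),
                        }
                    )
                    continue

                g = world.generics[int(rng.integers(len(world.generics)))]
                if rng.random() < cfg.combination_rate and len(world.generics) > 1:
                    partner = g
                    while partner == g:
                        partner = world.generics[
                            int(rng.integers(len(world.generics)))
                        ]
                    text = f"{g}-{partner}"
                    ops = ["combination"]
                    if rng.random() < cfg.dose_suffix_rate:
                        dose = _DOSES[int(rng.integers(len(_DOSES)))]
                        text = f"{text} {dose} mg"
                        ops.append("dose_suffix")
                    if rng.random() < cfg.case_noise_rate:
                        text = _random_case(rng, text)
                        ops.append("case")
                else:
                    surface = g
                    ops = []
                    if rng.random() < cfg.brand_swap_rate and world.trade_of[g]:
                        surface = world.trade_of[g][
                            int(rng.integers(len(world.trade_of[g])))
                        ]
                        ops.append("brand_swap")
                    text, more = corrupt_name(
                        surface, cfg, rng, world.variant_pools.get(surface, ())
                    )
                    ops.extend(more)
                entries.append(RawMedicationEntry(rid, pid, vid, text))
                truth_rows.append(
                    {
                        "record_id": rid, "participant_id": pid,
                        "visit_id": vid, "raw_text": text,
                        "excluded": False, "true_canonical": g,
                        "true_class_num": world.class_of[g],
                        "corruption": "|".join(ops),
                    }
                )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_entries": len(entries),
        "n_excluded_truth": int(truth["excluded"].sum()),
        "n_generics": len(world.generics),
        "n_classes": cfg.n_classes,
    }
    return entries, truth, manifest


def truth_long(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth long-format exposure rows (eligible entries only)."""
    rows = truth[~truth["excluded"]]
    return pd.DataFrame(
        {
            "participant_id": rows["participant_id"],
            "visit_id": rows["visit_id"],
            "canonical_name": rows["true_canonical"],
            "AHFSClassNum": rows["true_class_num"],
            "class_label": "",
        }
    ).reset_index(drop=True)


def evaluate_recovery(
    results: Sequence[MatchResult],
    truth: pd.DataFrame,
    classmap: ClassificationMap | None = None,
    matrix: pd.DataFrame | None = None,
    truth_matrix: pd.DataFrame | None = None,
    matched_statuses: Sequence[str] = ("matched",),
) -> dict[str, float]:
    """Score pipeline output against the generator's ground truth.

    * precision — fraction of matched assignments whose canonical name is
      the true one;
    * recall — fraction of eligible (non-excluded) truths recovered as a
      correct match;
    * classification accuracy — over matched records, fraction whose
      assigned class set contains the true class;
    * exposure agreement — fraction of identical cells between the
      pipeline's wide matrix and the ground-truth matrix (when both given).
    """
    truth_by_id = {str(r.record_id): r for r in truth.itertuples()}
    unknown = [r.record_id for r in results if r.record_id not in truth_by_id]
    if unknown:
        raise ValidationError(
            f"results reference record_ids absent from ground truth: "
            f"{unknown[:5]}..."
        )

    matched = [r for r in results if r.status in matched_statuses]
    n_correct = sum(
        1 for r in matched
        if r.canonical_name == truth_by_id[r.record_id].true_canonical
    )
    n_eligible = int((~truth["excluded"]).sum())
    metrics: dict[str, float] = {
        "n_matched": float(len(matched)),
        "n_eligible": float(n_eligible),
        "standardization_precision": (
            n_correct / len(matched) if matched else float("nan")
        ),
        "standardization_recall": (
            n_correct / n_eligible if n_eligible else float("nan")
        ),
    }

    if classmap is not None:
        n_class_ok = 0
        n_class_total = 0
        for r in matched:
            t = truth_by_id[r.record_id]
            if not t.true_class_num:
                continue
            assignments = classmap.get(r.canonical_name or "")
            if assignments is None:
                continue
            n_class_total += 1
            if t.true_class_num in {a.ahfs_class_num for a in assignments}:
                n_class_ok += 1
        metrics["classification_accuracy"] = (
            n_class_ok / n_class_total if n_class_total else float("nan")
        )

    if matrix is not None and truth_matrix is not None:
        all_index = matrix.index.union(truth_matrix.index)
        all_cols = matrix.columns.union(truth_matrix.columns)
        a = matrix.reindex(index=all_index, columns=all_cols, fill_value=0)
        b = truth_matrix.reindex(index=all_index, columns=all_cols, fill_value=0)
        total = a.size
        metrics["exposure_agreement"] = (
            float((a.values == b.values).sum()) / total if total else float("nan")
        )
    return metrics
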