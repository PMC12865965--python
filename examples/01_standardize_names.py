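"""Standardize messy free-text medication names to canonical generics.

Builds a five-name lexicon and a handful of realistically messy entries
(case noise, a brand name, a misspelling, a combination product, an OTC
distractor), then runs the staged matcher and prints where each entry
landed and why.
"""

from medharmonize import (
    ExclusionList,
    StandardizationConfig,
    VariantDictionary,
    filter_exclusions,
    normalize,
    standardize_corpus,
)
from medharmonize.textnorm import RawMedicationEntry

lexicon = {
    "atorvastatin": "atorvastatin",
    "metformin": "metformin",
    "lisinopril": "lisinopril",
    "hydrochlorothiazide": "hydrochlorothiazide",
    "lipitor": "atorvastatin",  # brand -> generic
}
dictionary = VariantDictionary()
dictionary.add("lipator", "atorvastatin", source="expert-adjudicated",
               date="2025-03-01")
exclusions = ExclusionList.from_terms(["fish oil", "vitamin d"])

raw_texts = [
    "Lipitor 20 mg",            # brand, absolute match
    "METFORMIN",                # case noise, absolute match
    "lisinopril/HCTZ 20-12.5",  # combination -> primary ingredient
    "lipator",                  # recurrent misspelling -> dictionary
    "metformon",                # fresh one-edit typo -> fuzzy or queue
    "fish oil",                 # OTC supplement -> excluded up front
]
entries = [
    normalize(RawMedicationEntry(f"r{i}", "P1", "V1", text))
    for i, text in enumerate(raw_texts)
]

eligible, excluded = filter_exclusions(entries, exclusions)
out = standardize_corpus(
    eligible, lexicon, dictionary,
    StandardizationConfig(fuzzy_threshold=0.90, borderline_low=0.85),
)

print(f"{'raw text':<28}{'status':<12}{'canonical':<22}{'method':<14}stage")
for result in out.results:
    print(
        f"{result.entry.raw.raw_text:<28}{result.status:<12}"
        f"{result.canonical_name or '-':<22}{result.method or '-':<14}"
        f"{result.stage}"
    )
for entry, term in excluded:
    print(f"{entry.raw.raw_text:<28}{'excluded':<12}(matched OTC term {term!r})")

print()
print("Each eligible entry ends in exactly one terminal state; misspellings")
print("the reusable dictionary has seen before resolve without any fuzzy")
print("scoring, and unresolved typos wait in a queue for adjudication.")
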