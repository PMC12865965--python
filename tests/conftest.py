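"""Shared fixtures: a tiny hand-built reference set and a seeded synthetic world."""

from __future__ import annotations

import pandas as pd
import pytest

from medharmonize.reference_model import (
    AHFSReferenceSet,
    ExclusionList,
    VariantDictionary,
    load_reference_set,
)
from medharmonize.synthetic import GeneratorConfig, generate_corpus, generate_world

MINI_TABLES = {
    "generics": pd.DataFrame(
        {
            "UN": ["G1", "G2", "G3"],
            "GenDrugName": ["atorvastatin", "metformin", "lisinopril"],
            "AHFSClassID": ["C1", "C2", "C3"],
        }
    ),
    "tradenames": pd.DataFrame(
        {
            "UN": ["T1", "T2"],
            "Tradename": ["lipitor", "glucophage"],
            "GenDrugName": ["atorvastatin", "metformin"],
        }
    ),
    "scdf": pd.DataFrame(
        {
            "SCDF_STR": [
                "atorvastatin oral tablet",
                "metformin oral tablet",
                "lisinopril oral tablet",
            ],
            "SCDF_CUI": ["CUI1", "CUI2", "CUI3"],
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
        }
    ),
    "classes": pd.DataFrame(
        {
            "AHFSClassID": ["C1", "C2", "C3"],
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText": [
                "Antihyperlipidemic Agents",
                "Biguanides",
                "ACE Inhibitors",
            ],
        }
    ),
    "classes_extended": pd.DataFrame(
        {
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText_2": ["24:06", "68:20", "24:32"],
            "AHFSClassText_3": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText_4": ["24:06.08", "68:20.04", "24:32.04"],
        }
    ),
}


def write_mini_tables(directory, overrides=None):
    tables = dict(MINI_TABLES)
    if overrides:
        tables.update(overrides)
    paths = {}
    for name, df in tables.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


@pytest.fixture()
def mini_ref_paths(tmp_path):
    return write_mini_tables(tmp_path)


@pytest.fixture()
def mini_refset(mini_ref_paths) -> AHFSReferenceSet:
    return load_reference_set(mini_ref_paths)


@pytest.fixture()
def mini_exclusions() -> ExclusionList:
    return ExclusionList.from_terms(["vitamin d", "fish oil", "multivitamin"])


@pytest.fixture(scope="session")
def world():
    """A seeded synthetic reference world (shared read-only across tests)."""
    return generate_world(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def corpus(world):
    """The seeded 1,000-entry corpus with ground truth for the shared world."""
    return generate_corpus(world.config, world)


@pytest.fixture()
def fresh_dictionary(world) -> VariantDictionary:
    """A mutable copy of the world's seeded dictionary (tests may grow it)."""
    return VariantDictionary(
        dict(world.dictionary.entries), dict(world.dictionary.provenance)
    )
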