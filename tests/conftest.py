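import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, database=None)
settings.load_profile("ci")

from engraftment.io_tables import (
    CountTable,
    RANKS,
    SampleMetadata,
    TaxonomyTable,
    align,
)


@pytest.fixture
def toy_counts() -> CountTable:
    """3 ASVs x 4 samples with hand-summed depths 10, 10, 20, 7."""
    df = pd.DataFrame(
        {
            "s1": [5, 3, 2],
            "s2": [0, 4, 6],
            "s3": [10, 5, 5],
            "s4": [1, 2, 4],
        },
        index=["asvA", "asvB", "asvC"],
    )
    return CountTable(df)


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    rows = {
        "asvA": dict.fromkeys(RANKS, "unclassified")
        | {"domain": "Bacteria", "phylum": "Firmicutes", "genus": "Blautia"},
        "asvB": dict.fromkeys(RANKS, "unclassified")
        | {"domain": "Bacteria", "phylum": "Firmicutes", "genus": "Blautia"},
        "asvC": dict.fromkeys(RANKS, "unclassified")
        | {"domain": "Bacteria", "phylum": "Bacteroidota", "genus": "Bacteroides"},
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def make_metadata(sample_ids, groups, roles=None, kinds=None) -> SampleMetadata:
    roles = roles or ["recipient"] * len(sample_ids)
    kinds = kinds or ["biological"] * len(sample_ids)
    return SampleMetadata(
        pd.DataFrame(
            {
                "group": groups,
                "role": roles,
                "host_genotype": ["WT"] * len(sample_ids),
                "transplant_event": ["t1"] * len(sample_ids),
                "generation": [1] * len(sample_ids),
                "replicate_kind": kinds,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture
def toy_bundle(toy_counts, toy_taxonomy):
    meta = make_metadata(
        ["s1", "s2", "s3", "s4"],
        ["inp", "inp", "rec", "rec"],
        roles=["input", "input", "recipient", "recipient"],
        kinds=["technical", "technical", "biological", "biological"],
    )
    return align(toy_counts, toy_taxonomy, meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
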