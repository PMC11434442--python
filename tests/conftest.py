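import numpy as np
import pandas as pd
import pytest

from rhizonet.datasets import AbundanceTable, SampleMetadata, TaxonomyTable
from rhizonet.simulate import generate, preset_paper_like


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        [[10, 0], [5, 5], [0, 20]],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB"],
    )


@pytest.fixture
def toy_table(toy_counts):
    return AbundanceTable(toy_counts)


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "domestication_group": ["wild", "wild", "modern", "modern"],
            "fertilization": ["unfertilized"] * 4,
            "replicate": [0, 1, 0, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(frame)


@pytest.fixture
def simple_taxonomy():
    frame = pd.DataFrame(
        {"phylum": ["P1", "P1", "P2"], "species": ["a", "b", "c"]},
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
    )
    return TaxonomyTable(frame)


@pytest.fixture(scope="session")
def paper_like_dataset():
    """One shared paper-like synthetic dataset (seed 1)."""
    return generate(preset_paper_like(seed=1))


def random_graph_edges(rng, n, p):
    """Erdos-Renyi edge list over node labels 0..n-1."""
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j))
    return edges
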