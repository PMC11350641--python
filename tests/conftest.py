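import numpy as np
import pytest

from trophicniche import (
    AbundanceTable,
    CompositionProfile,
    RunConfig,
    SampleMetadata,
    TaxonRecord,
)


def make_profile(props, group="g", rank="genus", items=None):
    props = np.asarray(props, dtype=float)
    if items is None:
        items = tuple(f"t{i}" for i in range(props.size))
    return CompositionProfile(group=group, rank=rank, items=tuple(items),
                              proportions=props)


def random_profile(rng, n_items=None, items=None):
    n = n_items or rng.integers(2, 20)
    p = rng.dirichlet(np.ones(n) * rng.uniform(0.3, 3.0))
    return make_profile(p, items=items[:n] if items else None)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def small_table():
    """2 samples x 3 genus-level taxa with full lineages."""
    taxa = [
        TaxonRecord(
            taxon_id=f"G{i}",
            lineage={
                "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Insecta",
                "order": "Lepidoptera" if i < 2 else "Diptera",
                "family": f"Fam{i}", "genus": f"G{i}",
            },
        )
        for i in range(3)
    ]
    counts = np.array([[5, 7, 3], [2, 0, 8]])
    return AbundanceTable(samples=["s1", "s2"], taxa=taxa, counts=counts)


@pytest.fixture
def small_metadata():
    return [
        SampleMetadata("s1", "SpeciesA", 2000, "COI"),
        SampleMetadata("s2", "SpeciesB", 2400, "COI"),
    ]
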