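import numpy as np
import pandas as pd
import pytest

from bifidopart.preprocess import CountTable
from bifidopart.synthetic import (
    CohortConfig,
    MagSimConfig,
    default_components,
    generate_mag_collection,
    generate_partitioned_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230331)


@pytest.fixture(scope="session")
def small_cohort():
    """400 samples from two well-separated components, no background noise."""
    cfg = CohortConfig(
        n_samples=400,
        dmm_components=default_components(k=2),
        n_background_taxa=0,
        partition_effects={},
        seed=11,
    )
    return generate_partitioned_cohort(cfg)


@pytest.fixture(scope="session")
def small_mags():
    """Two species, 32 MAGs each, full completeness, planted cassette."""
    cfg = MagSimConfig(
        n_species=2,
        n_mags_per_species=32,
        genes_per_genome=40,
        gene_length=400,
        completeness_range=(100.0, 100.0),
        seed=5,
    )
    return generate_mag_collection(cfg)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {
            "s1": [3, 4, 10, 0],
            "s2": [1, 0, 5, 2],
            "s3": [0, 0, 7, 1],
        },
        index=["Bifidobacterium_longum", "Bifidobacterium_breve", "Escherichia_coli", "Roseburia_faecis"],
    )
    taxonomy = {
        "Bifidobacterium_longum": "Bifidobacterium",
        "Bifidobacterium_breve": "Bifidobacterium",
        "Escherichia_coli": "Escherichia",
        "Roseburia_faecis": "Roseburia",
    }
    return CountTable(counts, taxonomy)
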