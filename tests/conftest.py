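"""Shared fixtures.

The synthetic atlas (six NB-count datasets, five subtypes, batch shifts) is
expensive to build, so it is constructed once per session and shared; tests
must not mutate it (reference immutability is itself under test).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from tcellproj import ExpressionDataset, SimulationConfig, generate_synthetic_atlas_inputs
from tcellproj.atlas import AtlasBuilder, annotate_clusters
from tcellproj.preprocess import normalize_counts
from tcellproj.simulate import marker_genes_of


def make_dataset(counts, genes=None, cells=None, species="mouse", meta=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionDataset(
        gene_ids=genes, cell_ids=cells, counts=sparse.csr_matrix(counts),
        species=species, cell_meta=meta,
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()  # packaged defaults, seed 42


@pytest.fixture(scope="session")
def sim_data(sim_config):
    return generate_synthetic_atlas_inputs(sim_config)


@pytest.fixture(scope="session")
def sim_datasets(sim_data):
    return sim_data[0]


@pytest.fixture(scope="session")
def sim_truth(sim_data):
    return sim_data[1]


@pytest.fixture(scope="session")
def subtype_signatures(sim_config):
    return {f"S{k}": marker_genes_of(sim_config, k)
            for k in range(sim_config.n_subtypes)}


@pytest.fixture(scope="session")
def builder():
    return AtlasBuilder(random_state=0)


@pytest.fixture(scope="session")
def atlas(sim_datasets, subtype_signatures, builder):
    """Synthetic reference atlas with marker-annotated functional clusters."""
    a = AtlasBuilder(random_state=0).fit(sim_datasets).atlas_
    a.labels = annotate_clusters(a, subtype_signatures)
    a.subtype_order = sorted(set(a.labels))
    return a


@pytest.fixture(scope="session")
def normalized_datasets(sim_datasets):
    return [normalize_counts(d) for d in sim_datasets]


@pytest.fixture(scope="session")
def cv_metrics(sim_datasets, atlas):
    """Half-sample holdout benchmark on the packaged simulation (run once)."""
    from tcellproj.benchmark import crossvalidate_projection

    return crossvalidate_projection(
        sim_datasets, AtlasBuilder(random_state=0), seed=0,
        labels=atlas.labels, mode="drop")
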