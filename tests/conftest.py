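import numpy as np
import pandas as pd
import pytest

import methylink as ml
from methylink.simulate import sample_ids


@pytest.fixture(scope="session")
def small_config():
    return ml.SimulationConfig(
        n_samples_per_group=(12, 14), n_genes=80, n_cpgs=600,
        chrom_sizes={"chr1": 1_200_000, "chr2": 800_000}, seed=42,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return ml.generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_methylome(small_config, small_annotation):
    genes, islands = small_annotation
    meth, unmeth, sites, truth = ml.simulate_methylation(
        small_config, genes, islands
    )
    ids, groups = sample_ids(small_config)
    return ml.CpGCountMatrix(meth, unmeth, sites), groups, truth


@pytest.fixture(scope="session")
def small_expression(small_config, small_annotation):
    genes, _ = small_annotation
    counts, covariates, truth = ml.simulate_expression(small_config, genes)
    return counts, covariates, truth


def make_matrix(meth: dict, unmeth: dict, chroms=None):
    """Build a CpGCountMatrix from {site: [counts per sample]} dicts."""
    meth_df = pd.DataFrame(meth).T
    unmeth_df = pd.DataFrame(unmeth).T
    n = meth_df.shape[1]
    meth_df.columns = unmeth_df.columns = [f"S{i + 1}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": [chroms[s] if chroms else s.split(":")[0]
                      for s in meth_df.index],
            "pos": [int(s.split(":")[1]) for s in meth_df.index],
            "strand": "+",
        },
        index=meth_df.index,
    )
    sites.index.name = "site"
    return ml.CpGCountMatrix(meth_df, unmeth_df, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
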