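import numpy as np
import pandas as pd
import pytest

from conetwork import simdata, workflow
from conetwork.netbuild import NetworkConfig
from conetwork.query import NetworkBundle


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_samples=150,
        n_modules=3,
        genes_per_module=35,
        n_background_genes=60,
        weight_range=(0.7, 0.9),
        n_traits=4,
        trait_loading=0.6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_ds(small_config):
    return simdata.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_ds):
    return workflow.run_pipeline(
        small_ds.expression, None, None, NetworkConfig(mode="signed")
    )


@pytest.fixture(scope="session")
def small_bundle(small_ds, small_result):
    return NetworkBundle(
        adjacency=small_result.adjacency,
        labels=small_result.labels,
        membership=small_result.membership,
        eigengenes=small_result.eigengenes,
        annotation=small_ds.annotation,
        config=small_result.config,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_expression(rng, n_genes=10, n_samples=20):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
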