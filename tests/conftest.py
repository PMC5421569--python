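import dataclasses

import pytest

from mixcall import SimulationConfig, call_expression, generate_matrix
from mixcall.mixture import EMConfig

# Small geometry used across tests: 60 samples (20 focal), 300 genes,
# 20-gene panel with the planted gene positive in 8 of 20 focal samples.
SMALL = SimulationConfig(
    n_samples=60,
    n_genes=300,
    n_panel_genes=20,
    tissue_labels={"melanoma": 20 / 60, "other": 40 / 60},
    planted_penetrance=0.4,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return generate_matrix(small_config)


@pytest.fixture(scope="session")
def small_calls(small_config, small_fixture):
    matrix, _ = small_fixture
    return call_expression(
        matrix,
        small_config.panel_gene_ids(),
        list(small_config.effector_gene_ids),
        em=EMConfig(seed=3),
    )


def tweak(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
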