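import dataclasses

import numpy as np
import pytest

from sanepool.model import ModelConfig
from sanepool.synthetic import SyntheticConfig, cohort_networks, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# a deliberately small cohort for fast pipeline tests
TINY = SyntheticConfig(
    n_genes=40, n_cell_lines=3, n_drugs=6, targets_per_drug=4,
    planted_module_size=6, base_edge_density=0.08, seed=7,
)

TINY_MODEL = dict(hidden_dims=(8, 8), k_schedule=(16, 8))


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(TINY)


@pytest.fixture(scope="session")
def tiny_networks(tiny_cohort):
    vocab, nets = cohort_networks(tiny_cohort)
    return vocab, nets


@pytest.fixture
def tiny_model_config():
    return ModelConfig(**TINY_MODEL)


@pytest.fixture
def desk_config():
    return dataclasses.replace(SyntheticConfig(), seed=3)
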