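import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rnu4kit.simulate import SimulationConfig, generate_gene_and_scores


@pytest.fixture(scope="session")
def gene():
    """One deterministic synthetic gene + scores shared across tests."""
    return generate_gene_and_scores(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def model(gene):
    return gene.model


@pytest.fixture(scope="session")
def alignment(gene):
    return gene.alignment


@pytest.fixture(scope="session")
def score_table(gene):
    return gene.scores


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
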