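import numpy as np
import pytest

from epidomains import Genome, generate_scenario, ScenarioConfig


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (seed 7), shared across tests."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
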