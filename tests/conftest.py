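import pytest

from otocost import MCMCConfig, derive_subseed
from otocost.synthetic import reference_evidence, reference_scenario


@pytest.fixture(scope="session")
def evidence():
    """Evidence records of the reference scenario, keyed by label."""
    return {r.label: r for r in reference_evidence()}


@pytest.fixture(scope="session")
def scenario():
    return reference_scenario(seed=1)


@pytest.fixture
def mcmc_config():
    """Default-settings chain config with a per-label deterministic seed."""

    def make(label: str, seed: int = 1) -> MCMCConfig:
        return MCMCConfig(seed=derive_subseed(seed, label))

    return make
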