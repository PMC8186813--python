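import numpy as np
import pytest

from srnaevol import (
    FitnessShape,
    SRNAParams,
    generate_scenario,
    optimize_transcription,
)


@pytest.fixture(scope="session")
def shape() -> FitnessShape:
    return FitnessShape()


@pytest.fixture(scope="session")
def params() -> SRNAParams:
    """Wildtype within-generation rates (no amplification)."""
    return SRNAParams()


@pytest.fixture(scope="session")
def mu_opt() -> float:
    """Wildtype transcription optimum, computed once per session."""
    return optimize_transcription().mu


@pytest.fixture(scope="session")
def opt_params(mu_opt) -> SRNAParams:
    return SRNAParams(mu=mu_opt)


@pytest.fixture(scope="session")
def scenario_k9():
    return generate_scenario(G=20, k=9, seed=3)


@pytest.fixture(scope="session")
def scenario_k2():
    return generate_scenario(G=20, k=2, seed=5)


@pytest.fixture(scope="session")
def scenario_k17():
    return generate_scenario(G=20, k=17, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
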