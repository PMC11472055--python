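import numpy as np
import pytest

from twinpzm.signatures import load_packaged_signatures
from twinpzm.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def signatures():
    return load_packaged_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """Four pairs, two artefact-prone, with truth — reused across tests."""
    cfg = SimulationConfig(
        n_pairs=4,
        n_germline_sites=2000,
        n_pzm=40,
        noise_rate=[5.0, 5.0, 300.0, 300.0],
        ages=[30, 45, 60, 75],
        sexes=["M", "F", "M", "F"],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Three clean pairs: discordant sites are exactly the truth PZMs."""
    cfg = SimulationConfig(
        n_pairs=3,
        n_germline_sites=1500,
        n_pzm=25,
        noise_rate=0.0,
        ages=[25, 50, 70],
        sexes=["F", "M", "F"],
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
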