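import numpy as np
import pytest

from schichub import synthetic as synth
from schichub.genome import build_genome


@pytest.fixture(scope="session")
def assembly():
    return build_genome(2, 10_000_000, 100_000)


@pytest.fixture(scope="session")
def conformation(assembly):
    return synth.simulate_conformation(assembly, 0.4, seed=7)


@pytest.fixture(scope="session")
def contacts(assembly, conformation):
    df, _ = synth.sample_contacts(conformation, assembly, 2000, seed=8)
    return df


@pytest.fixture(scope="session")
def small_ensemble(assembly, conformation):
    """Jittered replicas of the true conformation (synthetic ensemble)."""
    return synth.ensemble_from_truth(assembly, conformation, n_models=4, jitter=0.05, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
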