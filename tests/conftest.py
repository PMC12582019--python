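import numpy as np
import pytest

from g4fold import TwoStateModel, simulate_ensemble, simulate_fret_population


@pytest.fixture(scope="session")
def bimodal_values():
    """Fixed-seed two-population FRET values (37/63 at 0.49/0.81)."""
    return simulate_fret_population(
        means=[0.49, 0.81], sds=[0.05, 0.05], weights=[0.37, 0.63],
        n_molecules=300, seed=11,
    )


@pytest.fixture(scope="session")
def unimodal_values():
    return simulate_fret_population(
        means=[0.41], sds=[0.05], weights=[1.0], n_molecules=2000, seed=7
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """50 molecules at the 25 mM K+ kinetic regime, no bleaching."""
    model = TwoStateModel(seed=5, n_frames=300)
    return model, simulate_ensemble(model, 50)


@pytest.fixture(scope="session")
def noiseless_model():
    return TwoStateModel(
        sigma_e_low=0.0, sigma_e_high=0.0, sigma_channel=0.0,
        bg_donor=0.0, bg_acceptor=0.0, seed=2, n_frames=400,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
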