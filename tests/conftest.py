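import numpy as np
import pytest

from dyadcoupling import spectral, synth


@pytest.fixture(scope="session")
def short_schedule():
    """Compact acquisition block: 8+8 trials, 62.5% reinforcement."""
    return synth.make_schedule(8, 8, 0.625, seed=11, start_s=40.0,
                               iti_range_s=(4.0, 6.0))


@pytest.fixture(scope="session")
def delta():
    return spectral.DEFAULT_BANDS["delta"]


@pytest.fixture(scope="session")
def planted_dyad(short_schedule, delta):
    """One dyad with a strongly coupled pair (D00-O00, kappa=0.9)."""
    plantings = [synth.PlantedCoupling("D00", "O00", kappa=0.9)]
    return synth.simulate_dyad_signals(short_schedule, plantings, band=delta,
                                       fs=250.0, n_channels=2, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
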