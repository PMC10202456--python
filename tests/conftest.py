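import numpy as np
import pytest

from icman.synthetic_ic import make_population, make_probe_stimulus, simulate_response


@pytest.fixture(scope="session")
def probe_20s():
    """A 20 s spectrally rich probe stimulus (about 15k bins)."""
    return make_probe_stimulus(20.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(probe_20s):
    """Three-trial synthetic recording from a 24-unit, 4-dim population."""
    pop = make_population(n_units=24, signal_dim=4, signal_var_fraction=0.4, seed=3)
    rec = simulate_response(probe_20s, pop, n_trials=3, seed=4)
    return pop, rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
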