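import numpy as np
import pandas as pd
import pytest

from multicorr import activation_spec, inhibition_spec, mixture, simulate

#: canonical seed derivation for the demonstration mixture: activation at s,
#: inhibition at s+1, shuffle at s+2
DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_mixture() -> pd.DataFrame:
    """The seeded default mixture (X, Y, Z columns), 500 samples per model."""
    act = simulate(activation_spec(seed=DEFAULT_SEED))
    inh = simulate(inhibition_spec(seed=DEFAULT_SEED + 1))
    return mixture(act, inh, seed=DEFAULT_SEED + 2).to_frame()[["X", "Y", "Z"]]


@pytest.fixture(scope="session")
def default_mixture_labeled():
    act = simulate(activation_spec(seed=DEFAULT_SEED))
    inh = simulate(inhibition_spec(seed=DEFAULT_SEED + 1))
    return mixture(act, inh, seed=DEFAULT_SEED + 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
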