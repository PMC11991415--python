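import numpy as np
import pytest

import leafcal as lc


@pytest.fixture(scope="session")
def profiles():
    return lc.default_profiles()


@pytest.fixture(scope="session")
def mango_pop(profiles):
    """100-leaf mango population on all three layouts (shared, read-only)."""
    return lc.simulate_population(profiles["mango"], 100, seed=11)


@pytest.fixture(scope="session")
def mango_vis6(mango_pop):
    return mango_pop.dataset("vis6")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
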