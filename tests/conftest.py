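import numpy as np
import pytest

from halfsibgwas import simulate


@pytest.fixture(scope="session")
def small_pop():
    """A small null half-sib population shared by read-only tests."""
    cfg = simulate.null_config(n_families=20, family_size=5, n_snps=60, seed=3)
    return simulate.simulate_population(cfg)


@pytest.fixture(scope="session")
def confounded_pop():
    """An elite-confounded population (diverged elite family, shifted mean)."""
    return simulate.simulate_population(simulate.confounded_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
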