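import numpy as np
import pandas as pd
import pytest

from florsel.synthetic import (
    derived_seeds_per_plant,
    make_preset,
    simulate_population,
)


@pytest.fixture(scope="session")
def barra():
    return make_preset("barra-like")


@pytest.fixture(scope="session")
def melide():
    return make_preset("melide-like")


@pytest.fixture(scope="session")
def barra_table(barra):
    """A large simulated table with the derived total seed production attached."""
    tab = simulate_population(barra, n=5000, seed=42)
    tab["seeds_per_plant"] = derived_seeds_per_plant(tab)
    return tab


@pytest.fixture(scope="session")
def melide_table(melide):
    tab = simulate_population(melide, n=5000, seed=43)
    tab["seeds_per_plant"] = derived_seeds_per_plant(tab)
    return tab


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain_data():
    """n x 3 data from the linear chain X -> M -> Y with known coefficients."""
    r = np.random.default_rng(7)
    n = 2000
    X = r.normal(0, 1.0, n)
    M = 0.5 * X + r.normal(0, 1.0, n)
    Y = 0.4 * M + r.normal(0, 1.0, n)
    return pd.DataFrame({"X": X, "M": M, "Y": Y})
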