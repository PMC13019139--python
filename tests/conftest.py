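import numpy as np
import pytest

from prostate_cea import default_parameters
from prostate_cea.markov import LifeTable
from prostate_cea.synthetic import default_life_table_spec, generate_life_table


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    """Calibrated synthetic Japanese-male-like mortality schedule."""
    return generate_life_table(default_life_table_spec())


@pytest.fixture(scope="session")
def zero_mortality_table():
    ages = np.arange(60, 121)
    return LifeTable(ages=ages, qx=np.zeros_like(ages, dtype=float))


@pytest.fixture(scope="session")
def flat_mortality_table():
    """Constant 1% annual death probability (hand-computable)."""
    ages = np.arange(60, 121)
    return LifeTable(ages=ages, qx=np.full(ages.shape, 0.01))
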