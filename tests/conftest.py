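import numpy as np
import pytest

from metsmarkov import MetabolicState, StateDistribution, load_fixture


@pytest.fixture(scope="session")
def men_matrix():
    return load_fixture("men_table2")


@pytest.fixture(scope="session")
def women_matrix():
    return load_fixture("women_table3")


@pytest.fixture(scope="session")
def uniform_start():
    return StateDistribution(np.full(8, 1 / 8))


@pytest.fixture(scope="session")
def no_component_start():
    return StateDistribution.point_mass(MetabolicState.NO_COMPONENT)
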