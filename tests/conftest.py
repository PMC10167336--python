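import numpy as np
import pytest

from morphoclade.discrete_evolution import build_q
from morphoclade.synthetic_data import (SimulationSpec, simulate_regimes,
                                        simulate_study, yule_tree)


@pytest.fixture(scope="session")
def small_tree():
    """32-tip pure-birth tree, unit height."""
    return yule_tree(32, seed=11)


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study shared across IO / alignment tests."""
    spec = SimulationSpec(n_species=12, n_extra_specimens=4, seed=7)
    specimens, ecology, trees, truth = simulate_study(spec)
    return {"specimens": specimens, "ecology": ecology, "trees": trees,
            "truth": truth}


@pytest.fixture(scope="session")
def two_state_map(small_tree):
    """A true two-regime character map on the session tree."""
    Q = build_q(np.array([0.6]), 2, "ER")
    return simulate_regimes(small_tree, Q, ["deep", "shallow"], seed=2)
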