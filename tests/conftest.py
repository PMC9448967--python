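import numpy as np
import pytest

import moltevo as mv


@pytest.fixture(scope="session")
def small_tree():
    return mv.simulate_yule_tree(6, seed=11)


@pytest.fixture(scope="session")
def mid_tree():
    return mv.simulate_yule_tree(50, seed=12)


@pytest.fixture(scope="session")
def dep_rates():
    return mv.DependentRates(
        q12=0.4, q21=0.2, q13=0.9, q31=0.1, q24=0.5, q42=0.3, q34=0.8, q43=0.6
    )


@pytest.fixture(scope="session")
def small_pair(small_tree, dep_rates):
    Q = mv.build_generator(dep_rates)
    return mv.simulate_ctmc_pair(small_tree, Q, root=0, seed=21)


@pytest.fixture(scope="session")
def mid_pair(mid_tree):
    Q = mv.build_generator(mv.IndependentRates(0.6, 0.6, 0.9, 0.9))
    return mv.simulate_ctmc_pair(mid_tree, Q, root=0, seed=22)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
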