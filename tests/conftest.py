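import numpy as np
import pytest

import activenematic as an


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Trigger the one-off numba compilation before any timed test body."""
    p = an.SimParams(L=8, C=0.5, beta_eps=1.0, burn_in_iterations=2,
                     measure_iterations=2, measure_stride=1, seed=0)
    an.run_simulation(p)


def make_state(L, sites, angles):
    """Build a LatticeState from explicit (x, y) sites and angles."""
    occ = np.zeros((L, L), dtype=np.int8)
    orient = np.full((L, L), np.nan)
    for (x, y), th in zip(sites, angles):
        occ[x, y] = 1
        orient[x, y] = th
    return an.LatticeState.from_fields(occ, orient)


def random_state(L, C, seed):
    return an.init_lattice(
        an.SimParams(L=L, C=C, beta_eps=1.0, burn_in_iterations=0,
                     measure_iterations=0), np.random.default_rng(seed))
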