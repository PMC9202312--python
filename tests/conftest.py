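"""Shared fixtures: small model systems and converged ground states.

Everything is generated programmatically and seeded; session scope keeps
the more expensive converged states shared across test modules.
"""

import numpy as np
import pytest

from rtcc.fci import DenseSystem
from rtcc.groundstate import solve_cc_ground_state, solve_omp2_ground_state
from rtcc.system import make_fixture, h2_sto3g

SEED = 7


@pytest.fixture(scope="session")
def ints2e():
    """Two electrons in four spin orbitals, random Hermitian model."""
    return make_fixture(SEED, 2, 2, coupling_scale=0.3)


@pytest.fixture(scope="session")
def ints2e3v():
    """Two electrons in five spin orbitals (odd virtual count)."""
    return make_fixture(11, 2, 3, coupling_scale=0.2)


@pytest.fixture(scope="session")
def h2():
    return h2_sto3g()


@pytest.fixture(scope="session")
def dense2e(ints2e):
    return DenseSystem(ints2e)


@pytest.fixture(scope="session")
def gs_ccsd(ints2e):
    return solve_cc_ground_state(ints2e, "ccsd")


@pytest.fixture(scope="session")
def gs_cc2(ints2e):
    return solve_cc_ground_state(ints2e, "cc2")


@pytest.fixture(scope="session")
def gs_cc2b(ints2e):
    return solve_cc_ground_state(ints2e, "cc2b")


@pytest.fixture(scope="session")
def gs_omp2(ints2e):
    return solve_omp2_ground_state(ints2e)


def random_antisym_t2(rng, n_occ, n_virt, scale=0.1, cplx=True):
    w = rng.normal(scale=scale, size=(n_virt, n_virt, n_occ, n_occ))
    if cplx:
        w = w + 1j * rng.normal(scale=scale, size=w.shape)
    w = w - w.transpose(1, 0, 2, 3)
    w = w - w.transpose(0, 1, 3, 2)
    return w / 2.0


@pytest.fixture()
def rng():
    return np.random.default_rng(3)
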