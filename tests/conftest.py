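"""Shared fixtures: small synthetic systems reused across the suite."""

import numpy as np
import pytest

import excidyn as xd


@pytest.fixture(scope="session")
def two_level():
    """Two-level system at 4 eV with unit z transition dipole."""
    system, states = xd.make_two_level(4.0, 1.0)
    return system, states


@pytest.fixture(scope="session")
def three_level_ladder():
    """Ladder analogue of a pump-probe experiment (energies in eV)."""
    system, states = xd.make_ladder([3.679, 4.791], [2.0, 1.5])
    return system, states


@pytest.fixture(scope="session")
def donor_acceptor():
    system, states, scheme = xd.make_donor_acceptor()
    return system, states, scheme


@pytest.fixture(scope="session")
def random_system():
    spec = xd.SyntheticSpec(n_ao=8, n_occ=3, n_vir=4, n_states=5,
                            n_fragments=2, seed=11)
    return xd.make_random_system(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
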