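import numpy as np
import pytest

from pepdock import EnergyParams
from pepdock.toys import make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Small toy complex shared across tests (seeded, deterministic)."""
    return make_toy_complex(receptor_size=40, peptide_length=6,
                            pocket_depth=4.0, rng=7)


@pytest.fixture(scope="session")
def small_toy():
    """An even smaller toy for the slower sampling tests."""
    return make_toy_complex(receptor_size=30, peptide_length=5,
                            pocket_depth=4.0, rng=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


def make_line_chain(n, spacing=3.8, role="peptide", names=None):
    """Straight CA trace along x with side centres along +y."""
    from pepdock.cg import CGChain

    ca = np.zeros((n, 3))
    ca[:, 0] = np.arange(n) * spacing
    cb = ca + np.array([0.0, 1.1, 0.0])
    sc = ca + np.array([0.0, 2.2, 0.0])
    names = names or ["ALA"] * n
    return CGChain(names, np.arange(1, n + 1), ca, cb, sc,
                   chain_id="P" if role == "peptide" else "A", role=role)
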