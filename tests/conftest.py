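import numpy as np
import pytest

from gotensor import FixtureSpec, GoParameters, make_toy_protein


@pytest.fixture(scope="session")
def go_params():
    return GoParameters()


@pytest.fixture(scope="session")
def helix20(go_params):
    """Ideal 20-residue helix fixture: (coords, topology)."""
    return make_toy_protein(FixtureSpec(kind="helix", n_residues=20), go_params)


@pytest.fixture(scope="session")
def coil10(go_params):
    """Seeded 10-residue self-avoiding coil: (coords, topology)."""
    return make_toy_protein(FixtureSpec(kind="random_coil", n_residues=10, seed=5), go_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
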