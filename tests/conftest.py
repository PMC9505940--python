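import numpy as np
import pytest

from pspgnm import load_packaged_potential
from pspgnm.fixtures import FixtureSpec, make_mutant_pair, make_toy_chain


@pytest.fixture(scope="session")
def mj():
    """The packaged Miyazawa-Jernigan contact potential."""
    return load_packaged_potential()


@pytest.fixture(scope="session")
def helix25(mj):
    structure, pdb_text = make_toy_chain(FixtureSpec(n_residues=25, seed=11))
    return structure


@pytest.fixture(scope="session")
def helix30(mj):
    structure, _ = make_toy_chain(FixtureSpec(n_residues=30, seed=4))
    return structure


@pytest.fixture(scope="session")
def mutant_pair(mj):
    """A 25-residue wildtype, its interior point mutant, and the spec."""
    return make_mutant_pair(FixtureSpec(n_residues=25, seed=2), 13)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
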