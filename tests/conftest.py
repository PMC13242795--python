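import numpy as np
import pytest

from pifgen.synthetic_data import Instance, MoleculeTemplate, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain_template():
    return MoleculeTemplate(topology="chain", n_atoms_range=(5, 8))


@pytest.fixture(scope="session")
def ring_template():
    return MoleculeTemplate(topology="ring", n_atoms_range=(5, 7))


@pytest.fixture(scope="session")
def small_dataset(chain_template) -> list:
    """Eight pocket-paired chain ligands."""
    return make_dataset(chain_template, 8, seed=7)


@pytest.fixture(scope="session")
def mixed_dataset(chain_template, ring_template) -> list:
    data = make_dataset(chain_template, 10, seed=7) + make_dataset(
        ring_template, 10, seed=8
    )
    return [Instance(id=i, molecule=inst.molecule, pocket=inst.pocket)
            for i, inst in enumerate(data)]
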