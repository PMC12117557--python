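import numpy as np
import pytest
from hypothesis import settings

from hybridscreen.chem_io import Molecule, MoleculeSet

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")
from hybridscreen.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def toy_set() -> MoleculeSet:
    """Six hand-picked molecules with labels, mixed scaffolds."""
    records = [
        ("c1ccccc1C", "tol", 1),        # toluene
        ("c1ccccc1O", "phe", 0),        # phenol
        ("c1ccncc1", "pyr", 1),         # pyridine
        ("CCCCCC", "hex", 0),           # n-hexane (acyclic)
        ("C1CCNCC1", "pip", 0),         # piperidine
        ("c1ccc2ccccc2c1", "nap", 1),   # naphthalene
    ]
    return MoleculeSet([Molecule.from_smiles(s, i, y) for s, i, y in records],
                       name="toy")


@pytest.fixture(scope="session")
def small_synth():
    """A small generated screening set shared across tests."""
    return generate_dataset(SynthConfig(n_molecules=400, active_fraction=0.05,
                                        n_families=8, seed=11))


@pytest.fixture(scope="session")
def synth_3d():
    """A tiny generated set with seeded 3D conformers."""
    return generate_dataset(SynthConfig(n_molecules=40, active_fraction=0.2,
                                        n_families=5, seed=7, emit_3d=True))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
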