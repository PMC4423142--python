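import numpy as np
import pytest

from tyroqsar import Atom, Molecule, make_point_cloud_molecule


def atom(element, x, y, z, Z=None):
    numbers = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "Cl": 17}
    return Atom(element, Z if Z is not None else numbers[element],
                np.array([x, y, z], dtype=float))


@pytest.fixture
def diatomic_cn():
    """Heteronuclear diatomic C-N, 1.2 Å apart."""
    return Molecule("cn", [atom("C", 0, 0, 0), atom("N", 1.2, 0, 0)],
                    [(0, 1, 1.0)])


@pytest.fixture
def path4():
    """Four-carbon path a-b-c-d with unit spacing."""
    atoms = [atom("C", float(i), 0, 0) for i in range(4)]
    return Molecule("path4", atoms, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])


@pytest.fixture
def methane_star():
    """One carbon bonded to four identical hydrogens (tetrahedral-ish)."""
    atoms = [atom("C", 0, 0, 0),
             atom("H", 1.09, 0, 0), atom("H", -0.36, 1.03, 0),
             atom("H", -0.36, -0.51, 0.89), atom("H", -0.36, -0.51, -0.89)]
    return Molecule("methane", atoms, [(0, i, 1.0) for i in range(1, 5)])


@pytest.fixture
def cloud_factory():
    """Seeded random pseudo-molecule factory (connected spanning tree)."""
    def make(seed, n_atoms=8, elements=("C", "N", "O", "H", "S")):
        return make_point_cloud_molecule(n_atoms=n_atoms, elements=elements,
                                         seed=seed)
    return make


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
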