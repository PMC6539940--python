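import numpy as np
import pytest

from shpcvm import Atom, Molecule, normalize_pose


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated unit-variance Gaussian blobs at ±(3,3), n = 200."""
    rng = np.random.default_rng(42)
    n = 200
    X = np.vstack([rng.normal((3, 3), 1.0, (n // 2, 2)),
                   rng.normal((-3, -3), 1.0, (n // 2, 2))])
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture
def dumbbell():
    """Two carbon spheres on the z axis, pose-normalized."""
    atoms = (Atom("C", np.array([0.0, 0.0, 1.5]), 1.7),
             Atom("C", np.array([0.0, 0.0, -1.5]), 1.7))
    return normalize_pose(Molecule(id="dumbbell", atoms=atoms))


@pytest.fixture
def single_atom():
    return Molecule(id="c1", atoms=(Atom("C", np.zeros(3), 1.7),))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()


def rotate_molecule(mol: Molecule, R: np.ndarray) -> Molecule:
    atoms = tuple(Atom(a.element, R @ a.coords, a.vdw_radius,
                       a.occupancy, a.temp_factor) for a in mol.atoms)
    return Molecule(id=mol.id + "-rot", atoms=atoms)
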