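import numpy as np
import pytest

from mdpost.io import AtomRecord, Topology, Trajectory


def make_atom(serial, name="CA", element="C", mass=12.011, residue=0,
              resname="ALA", chain="A", resid=None, charge=0.0,
              rmin_half=1.7, epsilon=0.1, radius=1.5, screen=1.0):
    return AtomRecord(
        serial=serial, name=name, element=element, mass=mass, charge=charge,
        lj_rmin_half=rmin_half, lj_epsilon=epsilon, intrinsic_radius=radius,
        gb_screen=screen, residue_index=residue, residue_name=resname,
        chain_id=chain, resid=resid if resid is not None else residue + 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tetra_topology():
    """Four equal-mass atoms in one residue (generic geometry fixture)."""
    return Topology([make_atom(i + 1, name=f"C{i + 1}") for i in range(4)])


@pytest.fixture
def tetra_coords():
    return np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                     [0.0, 1.5, 0.0], [0.0, 0.0, 1.5]])


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


def apply_rigid(coords, rot, trans):
    return coords @ rot.T + trans
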