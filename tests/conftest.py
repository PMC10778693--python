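import numpy as np
import pytest

from ensdock.poses import LigandTopology, Pose
from ensdock.structures import Atom, Structure


def ca_structure(points, label="s", chain="A", resname="ALA"):
    """CA-only structure from an (n, 3) array; residue i+1 per point."""
    points = np.asarray(points, dtype=float)
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", resname=resname, chain=chain,
             resseq=i + 1, icode="", coord=points[i])
        for i in range(len(points))
    ]
    return Structure(label=label, atoms=atoms)


def rigid(coords, rotation, translation):
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def chain_topology():
    """A 5-heavy-atom chain ligand with distinct elements (no symmetry)."""
    atoms = (("C1", "C"), ("N2", "N"), ("C3", "C"), ("O4", "O"), ("S5", "S"))
    bonds = tuple((i, i + 1, 1.0) for i in range(4))
    return LigandTopology("chain", atoms, bonds)


def make_pose(topology, coords, score=-80.0, **kw):
    return Pose(ligand_id=topology.ligand_id, coords=np.asarray(coords, float),
                score=score, topology=topology, **kw)


@pytest.fixture
def chain_coords():
    return np.array(
        [[0.0, 0.0, 0.0], [1.4, 0.3, 0.0], [2.5, -0.6, 0.4], [3.9, -0.4, 0.1], [4.8, 0.8, 0.6]]
    )
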