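import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdgate.core import Structure, Trajectory
from mdgate import io as mio


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.normal(0, 10, 3)
    return rot, trans


def apply_rigid(positions, rot, trans):
    return positions @ rot.T + trans


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_structure():
    """Two-residue, two-chain toy structure with CA atoms and one ion."""
    return Structure(
        names=["CA", "CA", "CL"],
        elements=["C", "C", "CL"],
        resids=[1, 2, 3],
        resnames=["ALA", "GLY", "CLA"],
        chains=["A", "A", "I"],
        positions=[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [1.0, 1.0, 1.0]],
        box=[20.0, 20.0, 20.0, 90.0, 90.0, 90.0],
    )


@pytest.fixture
def transporter_fragment(tmp_path):
    """Synthetic stand-in for the transporter's initial-structure fragment.

    A hand-built PDB (not the experimental entry, which needs a download)
    carrying the chain-A Cα atoms used by the gating-distance and
    binding-site constructions: the gate tip (residue 201), core tip
    (residue 362, placed 22.0 Å away, the published initial separation)
    and the site anchors 128/391.
    """
    s = Structure(
        names=["CA", "CA", "CA", "CA"],
        elements=["C", "C", "C", "C"],
        resids=[128, 201, 362, 391],
        resnames=["PHE", "GLU", "ASP", "LEU"],
        chains=["A", "A", "A", "A"],
        positions=[[10.0, 5.0, 0.0], [0.0, 0.0, 0.0],
                   [22.0, 0.0, 0.0], [12.0, 5.0, 0.0]],
    )
    path = tmp_path / "synthetic_transporter_fragment.pdb"
    mio.write_structure(s, path)
    return path


def constant_trajectory(structure, n_frames=3):
    coords = np.tile(structure.positions, (n_frames, 1, 1))
    boxes = None
    if structure.box is not None:
        boxes = np.tile(structure.box, (n_frames, 1))
    return Trajectory(topology=structure, coordinates=coords, boxes=boxes)
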