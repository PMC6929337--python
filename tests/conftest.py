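import numpy as np
import pytest

from decoyrank.structure_io import StructureModel


def make_model(coords, model_id="m", residue_names=None):
    coords = np.asarray(coords, dtype=float)
    if residue_names is None:
        residue_names = ["ALA"] * len(coords)
    return StructureModel(id=model_id, residue_names=residue_names, coords=coords)


def random_rigid(coords, rng):
    """Apply a random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return coords @ R.T + t


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def zigzag10():
    """A mildly non-planar 10-residue CA-like trace."""
    rng = np.random.default_rng(7)
    coords = np.cumsum(
        np.tile([[3.0, 2.0, 0.5], [3.0, -2.0, -0.3]], (5, 1)), axis=0
    ) + rng.normal(0, 0.3, size=(10, 3))
    return make_model(coords, "zigzag10")


PDB_3RES = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""
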