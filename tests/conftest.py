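import numpy as np
import pytest

import rndcensus as rc
from rndcensus.io_model import StructureModel, chain_from_arrays

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      10.751   5.144  -4.308  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00           C
END
"""

ALTLOC_TIE_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50 10.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


def random_cloud_chain(n_atoms: int = 50, seed: int = 0, chain_id: str = "A",
                       center=(20.0, 0.0, 5.0), scale: float = 4.0):
    """A seeded random Cα point-cloud chain, offset from the origin."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(center) + rng.normal(0, scale, (n_atoms, 3))
    return chain_from_arrays(chain_id, range(1, n_atoms + 1), coords)


def rot_z(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def c3_trimer(n_atoms: int = 50, seed: int = 0, step: float = 120.0) -> StructureModel:
    """Trimer built by rotating one template by 0/step/2·step about z."""
    template = random_cloud_chain(n_atoms, seed)
    coords = np.array([r.atoms[0].position for r in template.residues])
    chains = []
    for k, cid in enumerate("ABC"):
        placed = coords @ rot_z(step * k).T
        chains.append(chain_from_arrays(cid, range(1, n_atoms + 1), placed))
    return StructureModel("trimer", chains)


def random_rotation(seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture(scope="session")
def default_library():
    spec = rc.SyntheticSpec(
        composition_distribution={"LTO": 1.0}, n_particles=1, seed=42
    )
    return rc.make_reference_library(spec)


@pytest.fixture(scope="session")
def o_star_library():
    spec = rc.SyntheticSpec(
        composition_distribution={"OO*O*": 1.0}, n_particles=1, seed=42
    )
    return rc.make_reference_library(spec)
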