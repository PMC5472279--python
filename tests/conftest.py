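import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from grasptools import hinge as hinge_mod
from grasptools import synthetic as syn


MINIMAL_PDB = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.100   1.900   0.500  1.00  0.00           C
ATOM      5  CA  SER A   3       6.800   3.100   1.200  1.00  0.00           C
HETATM    6  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.70  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.30  0.00           C
ATOM      3  CA  GLY A   2       3.000   1.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       5.000   2.000   1.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path) -> Path:
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path) -> Path:
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def two_state_models(ts: syn.TwoStateStructure):
    """Wrap a synthetic two-state pair as StructureModels + DomainDefinition."""
    n = ts.open_coords.shape[0]
    n1 = ts.domain1_index_range[1]
    chain = np.array(["A"] * n, dtype=object)
    resn = np.array(["ALA"] * n, dtype=object)
    res_id = np.arange(1, n + 1)
    a = hinge_mod.StructureModel(chain, res_id, resn, ts.open_coords, source="open")
    b = hinge_mod.StructureModel(chain.copy(), res_id.copy(), resn.copy(), ts.closed_coords, source="closed")
    dom = hinge_mod.DomainDefinition((1, n1), (n1 + 1, n))
    return a, b, dom
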