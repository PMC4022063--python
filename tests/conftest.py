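import numpy as np
import pytest

import pclfit as pf


@pytest.fixture(scope="session")
def colinear_backbone():
    """Three residues on a straight 3.8 Å-spaced line."""
    return pf.Backbone("AAA", np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]))


@pytest.fixture(scope="session")
def fcc_walk_20():
    return pf.lattice_walk_backbone(20, pf.FCC, seed=11)


@pytest.fixture(scope="session")
def small_coil():
    return pf.offlattice_backbone(12, seed=4)


TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LEU A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  1.00  0.50           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  1.00  0.50           C
ATOM      3  CA AGLY A   2       3.800   0.000   0.000  1.00  0.50           C
ATOM      4  CA BGLY A   2       4.300   0.000   0.000  1.00  0.50           C
ATOM      5  CA  LEU A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture(scope="session")
def altloc_pdb_text():
    return ALTLOC_PDB
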