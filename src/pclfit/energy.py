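"""Contact-based energy functions for lattice conformations.

The energy of a conformation is the sum, over residue pairs in lattice
contact, of a pairwise potential depending only on the amino-acid types:

    E(C) = sum_{i<j} contact(i, j) * energy(s_i, s_j)

Three models are bundled:

``hp-basic``
    The two-class HP model: −1 per hydrophobic–hydrophobic contact, 0
    otherwise.  The hydrophobic class is {A, C, F, I, L, M, V, W, Y}
    (overridable); every other residue, and the unknown code 'X', is polar.
``mj``
    The Miyazawa–Jernigan 20×20 statistical contact potential (1996
    contact-energy revision), loaded from a vendored text table.
``bre``
    A clearly-labelled *synthetic* stand-in with the shape and sign
    structure of an empirical contact potential (hydrophobicity-product
    construction; see the data file header).  Substitute the published
    matrix by loading it from a path in the same format.

Sequence-adjacent pairs (j = i+1) are excluded from contacts by default: on
the FCC lattice every bonded pair sits at contact distance, so they would
contribute a sequence-dependent constant that no search decision can change.
Pass ``include_adjacent=True`` for the literal all-pairs sum.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import Conformation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: default hydrophobic class for the HP model
HYDROPHOBIC = frozenset("ACFILMVWY")

MODEL_NAMES = ("hp-basic", "mj", "bre")
_MODEL_FILES = {"mj": "mj1996.txt", "bre": "bre_synthetic.txt"}


class EnergyModel:
    """A named symmetric pairwise contact potential over amino-acid types."""

    def __init__(self, name: str, potential: np.ndarray,
                 hp_class: dict[str, str] | None = None,
                 alphabet: str = AMINO_ACIDS):
        potential = np.asarray(potential, dtype=np.float64)
        if potential.shape != (len(alphabet), len(alphabet)):
            raise ValueError("potential must be square over the alphabet")
        if not np.allclose(potential, potential.T):
            raise ValueError(f"potential for {name!r} is not symmetric")
        self.name = name
        self.alphabet = alphabet
        self.potential = potential
        self.hp_class = hp_class or {}
        self._index = {a: i for i, a in enumerate(alphabet)}

    def pair_energy(self, a: str, b: str) -> float:
        """energy(a, b) for two 1-letter residue codes."""
        return float(self.potential[self._residue_index(a), self._residue_index(b)])

    def _residue_index(self, a: str) -> int:
        a = a.upper()
        if a not in self._index:
            if self.name == "hp-basic" and a == "X":
                # unknown residues are polar in the HP model
                return self._index["G"]
            raise KeyError(
                f"residue {a!r} is not in the {self.name!r} model alphabet"
            )
        return self._index[a]

    def sequence_potential(self, seq: str) -> np.ndarray:
        """n×n matrix of energy(s_i, s_j) for a fixed sequence (fast path)."""
        idx = np.array([self._residue_index(a) for a in seq])
        return self.potential[np.ix_(idx, idx)]

    def __repr__(self) -> str:
        return f"EnergyModel({self.name!r})"


def _hp_basic(hydrophobic=HYDROPHOBIC) -> EnergyModel:
    hset = frozenset(a.upper() for a in hydrophobic)
    pot = np.zeros((20, 20))
    for a in hset:
        for b in hset:
            pot[_AA_INDEX[a], _AA_INDEX[b]] = -1.0
    hp_class = {a: ("H" if a in hset else "P") for a in AMINO_ACIDS}
    hp_class["X"] = "P"
    return EnergyModel("hp-basic", pot, hp_class=hp_class)


def _read_table(text: str) -> tuple[str, np.ndarray]:
    rows, labels = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        labels.append(parts[0].upper())
        rows.append([float(x) for x in parts[1:]])
    mat = np.asarray(rows)
    if mat.shape != (len(labels), len(labels)):
        raise ValueError("potential table is not square")
    return "".join(labels), mat


def load_energy_model(name: str = "mj", path: str | Path | None = None) -> EnergyModel:
    """Load a bundled model by name, or any 20×20 table from ``path``.

    The file format is whitespace-delimited: comment lines start with '#',
    each data row is a 1-letter code followed by 20 energies, rows and
    columns in the same residue order.
    """
    if path is not None:
        alphabet, mat = _read_table(Path(path).read_text())
        order = np.argsort(list(alphabet))
        alphabet = "".join(sorted(alphabet))
        return EnergyModel(name, mat[np.ix_(order, order)], alphabet=alphabet)
    name = name.lower()
    if name == "hp-basic":
        return _hp_basic()
    if name not in _MODEL_FILES:
        raise KeyError(f"unknown energy model {name!r}; available: {MODEL_NAMES}")
    text = resources.files("pclfit.data").joinpath(_MODEL_FILES[name]).read_text()
    alphabet, mat = _read_table(text)
    return EnergyModel(name, mat, alphabet=alphabet)


def contact(i: int, j: int, C: Conformation, include_adjacent: bool = False) -> int:
    """1 iff residues i < j occupy neighboring lattice points.

    Bonded pairs (j = i+1) count only with ``include_adjacent=True``.
    """
    if i >= j:
        raise ValueError(f"contact requires i < j, got i={i}, j={j}")
    if j - i == 1 and not include_adjacent:
        return 0
    d = C.points[i] - C.points[j]
    return int(int(np.dot(d, d)) == C.lattice.contact_sqrdist)


def contact_matrix(C: Conformation, include_adjacent: bool = False) -> np.ndarray:
    """Boolean n×n matrix of lattice contacts (upper+lower, zero diagonal)."""
    sq = squareform(pdist(C.points.astype(np.float64), "sqeuclidean"), checks=False)
    mat = np.isclose(sq, C.lattice.contact_sqrdist)
    np.fill_diagonal(mat, False)
    if not include_adjacent:
        n = len(C)
        idx = np.arange(n - 1)
        mat[idx, idx + 1] = False
        mat[idx + 1, idx] = False
    return mat


def total_energy(C: Conformation, S: str, M: EnergyModel,
                 include_adjacent: bool = False) -> float:
    """E(C) = Σ_{i<j} contact(i,j) · energy(s_i, s_j)."""
    if len(S) != len(C):
        raise ValueError(f"sequence length {len(S)} != conformation length {len(C)}")
    pot = M.sequence_potential(S)
    mat = contact_matrix(C, include_adjacent=include_adjacent)
    return float(pot[mat].sum() / 2.0)
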