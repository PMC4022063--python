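"""Cubic and face-centered-cubic lattice geometry.

A lattice conformation places one point per residue on an integer lattice.
Two points are *neighbors* (in contact) when their difference is one of the
lattice's basis vectors.  The cubic lattice has 6 such vectors (squared
length 1), the FCC lattice 12 (squared length 2).  To map lattice units to
Ångströms, one neighbor step is normalized to 3.8 Å — the average Cα–Cα
distance of consecutive residues in real proteins — so the Å-per-unit scale
is 3.8 for cubic and 3.8/√2 for FCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CA_CA_BOND_ANGSTROM = 3.8

# Basis vectors in their canonical printed order; this order doubles as the
# FIFO tie-break order during chain growth.
_FCC_BASIS = (
    (1, 1, 0), (-1, -1, 0), (-1, 1, 0), (1, -1, 0),
    (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    (1, 0, 1), (-1, 0, 1), (1, 0, -1), (-1, 0, -1),
)
_CUBIC_BASIS = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


@dataclass(frozen=True)
class LatticeModel:
    """Geometry of one lattice type.

    Attributes
    ----------
    name : str
        ``"cubic"`` or ``"fcc"``.
    basis : numpy.ndarray
        Integer array of shape ``(k, 3)`` holding the neighbor vectors in
        canonical order (6 for cubic, 12 for FCC).
    contact_sqrdist : int
        Squared Euclidean length of a basis vector in lattice units
        (1 cubic, 2 FCC); two residues are in contact at exactly this
        squared distance.
    neighbor_length : float
        Euclidean length of one basis vector in lattice units.
    scale : float
        Å per lattice unit, fixed so one neighbor step spans 3.8 Å.
    """

    name: str
    basis: np.ndarray = field(repr=False)
    contact_sqrdist: int
    neighbor_length: float
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=np.int64))
        self.basis.setflags(write=False)
        tuples = tuple(tuple(v) for v in self.basis.tolist())
        object.__setattr__(self, "_basis_tuples", tuples)
        object.__setattr__(self, "_basis_set", frozenset(tuples))

    @property
    def basis_set(self) -> frozenset[tuple[int, int, int]]:
        return self._basis_set  # type: ignore[attr-defined]

    @property
    def basis_tuples(self) -> tuple[tuple[int, int, int], ...]:
        return self._basis_tuples  # type: ignore[attr-defined]


CUBIC = LatticeModel(
    name="cubic",
    basis=np.array(_CUBIC_BASIS),
    contact_sqrdist=1,
    neighbor_length=1.0,
    scale=CA_CA_BOND_ANGSTROM,
)

FCC = LatticeModel(
    name="fcc",
    basis=np.array(_FCC_BASIS),
    contact_sqrdist=2,
    neighbor_length=math.sqrt(2.0),
    scale=CA_CA_BOND_ANGSTROM / math.sqrt(2.0),
)

LATTICES: dict[str, LatticeModel] = {"cubic": CUBIC, "fcc": FCC}


def get_lattice(name: str) -> LatticeModel:
    """Return the lattice model registered under ``name`` (case-insensitive)."""
    try:
        return LATTICES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown lattice {name!r}; available: {sorted(LATTICES)}"
        ) from None


def sqrdist(p, q) -> int:
    """Exact integer squared Euclidean distance between two lattice points."""
    p = np.asarray(p, dtype=np.int64)
    q = np.asarray(q, dtype=np.int64)
    d = p - q
    return int(np.dot(d, d))


def are_neighbors(p, q, lat: LatticeModel) -> bool:
    """True iff ``q - p`` is one of ``lat``'s basis vectors.

    Equivalent to ``sqrdist(p, q) == lat.contact_sqrdist`` for these two
    lattices, but checked against the basis set for clarity.
    """
    d = tuple(int(b) - int(a) for a, b in zip(p, q))
    return d in lat.basis_set


def to_angstrom(p, lat: LatticeModel) -> np.ndarray:
    """Map lattice coordinates to Å so neighbor steps span exactly 3.8 Å.

    Accepts a single 3-vector or an ``(n, 3)`` array.
    """
    return np.asarray(p, dtype=np.float64) * lat.scale
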