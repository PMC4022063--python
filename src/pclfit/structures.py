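"""Native backbones, lattice conformations, PDB I/O and constraint checks.

A :class:`Backbone` is the fixed reference: the Cα trace of a native protein
chain (coordinates in Å) plus its one-letter sequence.  A
:class:`Conformation` is a candidate lattice structure: one integer lattice
point per residue, subject to three constraints — every point lies on the
lattice, consecutive points are lattice neighbors (*chain*), and no two
points coincide (*self-avoiding*).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

from .lattice import LatticeModel, to_angstrom

CHAIN_BREAK_ANGSTROM = 4.5

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


class PDBError(ValueError):
    """Raised for unusable PDB input (missing chain, too few Cα atoms...)."""


@dataclass
class Backbone:
    """Reference Cα trace: sequence ``s_1..s_n`` and coordinates ``b_1..b_n`` (Å)."""

    sequence: str
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.sequence)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"sequence length {n} does not match coords shape {self.coords.shape}"
            )
        if n < 2:
            raise ValueError("a backbone needs at least 2 residues")
        steps = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if not np.all(np.isfinite(steps)) or np.any(steps <= 0):
            raise ValueError("consecutive Cα positions must be distinct and finite")

    def __len__(self) -> int:
        return len(self.sequence)


class Conformation:
    """Lattice structure ``p_1..p_n``: integer points on a given lattice."""

    __slots__ = ("points", "lattice")

    def __init__(self, points, lattice: LatticeModel):
        self.points = np.asarray(points, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) integer array")
        self.lattice = lattice

    def __len__(self) -> int:
        return len(self.points)

    def coords_angstrom(self) -> np.ndarray:
        return to_angstrom(self.points, self.lattice)

    def copy(self) -> "Conformation":
        return Conformation(self.points.copy(), self.lattice)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Conformation)
            and self.lattice is other.lattice
            and np.array_equal(self.points, other.points)
        )

    def __repr__(self) -> str:
        return f"Conformation(n={len(self.points)}, lattice={self.lattice.name!r})"


@dataclass(frozen=True)
class Violation:
    """One broken constraint with the offending residue indices (0-based)."""

    kind: str  # 'chain' | 'self-avoiding' | 'domain'
    indices: tuple[int, ...]
    detail: str = ""


def validate(conf: Conformation) -> list[Violation]:
    """Check the chain, self-avoiding and coordinate-domain constraints.

    Returns an empty list iff the conformation is feasible; never raises.
    """
    pts = conf.points
    n = len(pts)
    out: list[Violation] = []
    steps = pts[1:] - pts[:-1]
    basis_set = conf.lattice.basis_set
    for i, s in enumerate(map(tuple, steps.tolist())):
        if s not in basis_set:
            out.append(Violation("chain", (i, i + 1), f"step {s} not a basis vector"))
    seen: dict[tuple[int, int, int], int] = {}
    for i, p in enumerate(map(tuple, pts.tolist())):
        if p in seen:
            out.append(Violation("self-avoiding", (seen[p], i), f"point {p} reused"))
        else:
            seen[p] = i
    if n and np.abs(pts).max() > n:
        bad = int(np.argmax(np.abs(pts).max(axis=1) > n))
        out.append(Violation("domain", (bad,), f"coordinate outside [-{n}, {n}]"))
    return out


def is_valid(conf: Conformation) -> bool:
    return not validate(conf)


# --------------------------------------------------------------------------
# PDB I/O (CA-only dialect)

def read_backbone(pdb_source, chain_id: str | None = None) -> Backbone:
    """Extract the Cα trace of one chain from PDB text or a file path.

    Uses the first MODEL only; the first chain when ``chain_id`` is None.
    Keeps altloc '' or 'A' conformers, ignores HETATM, maps unknown residues
    to 'X'.  Consecutive Cα atoms more than 4.5 Å apart trigger a chain-break
    warning (the fit treats the chain as continuous regardless).
    """
    text, label = _as_text(pdb_source)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or "protein", io.StringIO(text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBError("no MODEL found in PDB input") from None
    chains = {c.id: c for c in model}
    if not chains:
        raise PDBError("no chains found in PDB input")
    if chain_id is None:
        chain = next(iter(chains.values()))
    elif chain_id in chains:
        chain = chains[chain_id]
    else:
        raise PDBError(
            f"chain {chain_id!r} not found; available chains: {sorted(chains)}"
        )

    seq: list[str] = []
    coords: list[np.ndarray] = []
    for residue in chain:
        if residue.id[0] != " ":  # skip HETATM / waters
            continue
        ca = None
        for atom in residue:
            if atom.get_name() == "CA" and atom.get_altloc() in ("", "A", " "):
                ca = atom
                break
        if ca is None:
            continue
        seq.append(_3TO1.get(residue.get_resname().upper().strip(), "X"))
        coords.append(ca.get_coord().astype(np.float64))
    if len(coords) < 2:
        raise PDBError(
            f"chain {chain.id!r} has {len(coords)} Cα atoms; need at least 2"
        )
    arr = np.asarray(coords)
    gaps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    breaks = np.nonzero(gaps > CHAIN_BREAK_ANGSTROM)[0]
    if len(breaks):
        warnings.warn(
            f"chain {chain.id!r}: {len(breaks)} chain break(s) "
            f"(consecutive Cα > {CHAIN_BREAK_ANGSTROM} Å) at indices "
            f"{breaks.tolist()}; fitting as a continuous chain",
            stacklevel=2,
        )
    bid = f"{label}:{chain.id}" if label else str(chain.id)
    return Backbone(sequence="".join(seq), coords=arr, id=bid)


def _as_text(source) -> tuple[str, str]:
    """Return (pdb_text, label) from a path, file object or raw text."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "")
    s = str(source)
    if "\n" not in s and len(s) < 4096:
        from pathlib import Path

        p = Path(s)
        if p.exists():
            return p.read_text(), p.stem
    return s, ""


def write_conformation(conf: Conformation, seq: str, sink=None) -> str:
    """Emit a CA-only PDB trace for a lattice conformation.

    Coordinates are the Å-scaled lattice points; residues are numbered from 1.
    Returns the PDB text and writes it to ``sink`` (path or file object) when
    given.  Re-reading recovers the coordinates to PDB precision (1e-3 Å).
    """
    if len(seq) != len(conf):
        raise ValueError(
            f"sequence length {len(seq)} != conformation length {len(conf)}"
        )
    if len(conf) < 2:
        raise ValueError("conformation must have at least 2 points")
    bad = validate(conf)
    if bad:
        raise ValueError(f"invalid conformation: {bad[0].kind} at {bad[0].indices}")
    one_to_three = {v: k.upper() for k, v in protein_letters_3to1.items()}
    lines = []
    for i, (aa, xyz) in enumerate(zip(seq, conf.coords_angstrom()), start=1):
        res3 = one_to_three.get(aa.upper(), "UNK")
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            from pathlib import Path

            Path(sink).write_text(text)
    return text
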