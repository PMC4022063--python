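"""Synthetic backbones with known ground truth.

Three generators cover the regimes the fitting pipeline must handle:

* exact scaled lattice walks — a random self-avoiding walk mapped to Å and
  rigidly rotated/translated; the walk itself achieves dRMSD 0, so both
  chain growth and the search can be tested for exact recovery;
* perturbed walks — the same with isotropic Gaussian coordinate noise of
  scale sigma, for parameter-recovery-under-noise tests;
* off-lattice chains — random 3.8 Å-bond chains with an excluded-volume
  radius, emulating the geometry (though not the fold statistics) of real
  Cα traces for non-degenerate fitting tests.

All generators are deterministic under a fixed seed and write plain-text
PDB/FASTA fixtures on request.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import AMINO_ACIDS
from .lattice import CA_CA_BOND_ANGSTROM, LatticeModel, to_angstrom
from .structures import Backbone, Conformation, validate, write_conformation

#: minimum nonbonded distance in the off-lattice generator (Å)
CLASH_RADIUS = 3.0

_MAX_RESTARTS = 1000


def random_sequence(n: int, alphabet: str = AMINO_ACIDS, seed: int = 0) -> str:
    """Uniform i.i.d. residue sequence of length n over the given alphabet."""
    if n < 2:
        raise ValueError("sequence length must be >= 2")
    rng = np.random.default_rng(seed)
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def _random_saw(n: int, lat: LatticeModel, rng: np.random.Generator) -> np.ndarray:
    """Uniform-step random self-avoiding walk, restarting on dead ends."""
    for _ in range(_MAX_RESTARTS):
        pts = np.zeros((n, 3), dtype=np.int64)
        occ = {(0, 0, 0)}
        ok = True
        for k in range(1, n):
            cands = pts[k - 1] + lat.basis
            free = [q for q in map(tuple, cands.tolist()) if q not in occ]
            if not free:
                ok = False
                break
            q = free[rng.integers(len(free))]
            pts[k] = q
            occ.add(q)
        if ok:
            return pts
    raise RuntimeError(f"self-avoiding walk generation kept dead-ending at n={n}")


def _random_rigid_motion(
    coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)
    return coords @ rot.T + shift


def lattice_walk_backbone(
    n: int, lat: LatticeModel, seed: int = 0
) -> tuple[Backbone, Conformation]:
    """Backbone that is an exact (rigidly moved) scaled lattice walk.

    Returns the backbone and the generating walk; by construction
    ``drmsd(backbone, walk) == 0``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    pts = _random_saw(n, lat, rng)
    coords = _random_rigid_motion(to_angstrom(pts, lat), rng)
    seq = random_sequence(n, seed=int(rng.integers(2**31)))
    B = Backbone(sequence=seq, coords=coords, id=f"walk-{lat.name}-n{n}-s{seed}")
    return B, Conformation(pts, lat)


def perturbed_walk_backbone(
    n: int, lat: LatticeModel, sigma: float, seed: int = 0
) -> tuple[Backbone, Conformation, float]:
    """Exact-walk backbone with iid Gaussian noise of scale sigma (Å) per coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    B, conf = lattice_walk_backbone(n, lat, seed)
    rng = np.random.default_rng(seed + 77_000_001)
    coords = B.coords + rng.normal(0.0, sigma, size=B.coords.shape) if sigma else B.coords
    Bp = Backbone(
        sequence=B.sequence,
        coords=coords,
        id=f"pwalk-{lat.name}-n{n}-sig{sigma:g}-s{seed}",
    )
    return Bp, conf, sigma


def offlattice_backbone(
    n: int,
    seed: int = 0,
    bond: float = CA_CA_BOND_ANGSTROM,
    clash: float = CLASH_RADIUS,
) -> Backbone:
    """Random off-lattice chain: fixed 3.8 Å bonds, nonbonded pairs >= 3.0 Å.

    Directions are drawn uniformly on the sphere with rejection on clashes,
    giving a loose self-avoiding coil — geometrically plausible for a Cα
    trace without emulating real secondary structure.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RESTARTS):
        coords = np.zeros((n, 3))
        ok = True
        for k in range(1, n):
            placed = False
            for _try in range(100):
                v = rng.normal(size=3)
                v *= bond / np.linalg.norm(v)
                q = coords[k - 1] + v
                if k < 2 or np.linalg.norm(coords[: k - 1] - q, axis=1).min() >= clash:
                    coords[k] = q
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            seq = random_sequence(n, seed=int(rng.integers(2**31)))
            return Backbone(sequence=seq, coords=coords, id=f"coil-n{n}-s{seed}")
    raise RuntimeError("off-lattice chain generation kept dead-ending")


def write_fixture(
    outdir, B: Backbone, conf: Conformation | None = None, meta: dict | None = None
) -> dict:
    """Write a backbone as PDB + FASTA (plus manifest entry) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = B.id or "backbone"
    pdb_path = outdir / f"{stem}.pdb"
    _write_backbone_pdb(B, pdb_path)
    (outdir / f"{stem}.fasta").write_text(f">{stem}\n{B.sequence}\n")
    entry = {"id": stem, "n": len(B), "pdb": pdb_path.name, **(meta or {})}
    if conf is not None:
        assert not validate(conf)
        write_conformation(conf, B.sequence, outdir / f"{stem}.lattice.pdb")
        entry["lattice_pdb"] = f"{stem}.lattice.pdb"
    manifest = outdir / "manifest.json"
    entries = json.loads(manifest.read_text()) if manifest.exists() else []
    entries = [e for e in entries if e["id"] != stem] + [entry]
    manifest.write_text(json.dumps(entries, indent=1))
    return entry


def _write_backbone_pdb(B: Backbone, path) -> None:
    from Bio.Data.IUPACData import protein_letters_3to1

    one_to_three = {v: k.upper() for k, v in protein_letters_3to1.items()}
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(B.sequence, B.coords), start=1):
        res3 = one_to_three.get(aa.upper(), "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines += ["TER", "END"]
    Path(path).write_text("\n".join(lines) + "\n")
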