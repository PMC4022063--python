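"""dRMSD and its incremental evaluation.

The fitting objective is the distance-matrix RMSD

    dRMSD(B, C) = sqrt( sum_{i<j} (dist(b_i,b_j) - dist(p_i,p_j))^2 / (n(n-1)/2) )

computed over all residue pairs, with the lattice conformation C first scaled
to Å.  It needs no superposition: it is invariant under any rigid motion or
reflection of either structure.

Internally all comparisons use the squared-error sum; the square root is
taken only for reporting (a monotone transform, cheaper and numerically
stabler).  :class:`DistanceCache` supports simulating a move — recomputing
the objective after relocating a few residues at cost O(|moved| * n) instead
of O(n^2) — and committing it, which is what makes the local search cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, squareform

from .structures import Backbone, Conformation

#: a move must decrease the squared-error sum by more than this to count as
#: an improvement (guards against float-noise cycling)
IMPROVE_EPS = 1e-12

#: commits between full refreshes of the running squared-error sum
_REFRESH_EVERY = 256


def _pair_count(n: int) -> int:
    return n * (n - 1) // 2


def _dist_matrix(coords: np.ndarray) -> np.ndarray:
    return cdist(coords, coords)


def drmsd(B: Backbone, C: Conformation) -> float:
    """Distance-matrix RMSD between a backbone and a lattice conformation, in Å."""
    n = len(B)
    if len(C) != n:
        raise ValueError(f"length mismatch: backbone {n}, conformation {len(C)}")
    return drmsd_coords(B.coords, C.coords_angstrom())


def drmsd_coords(a: np.ndarray, b: np.ndarray) -> float:
    """dRMSD between two coordinate sets of equal length (both in Å)."""
    n = len(a)
    if len(b) != n:
        raise ValueError("coordinate sets differ in length")
    if n < 2:
        raise ValueError("need at least 2 points")
    da = _dist_matrix(np.asarray(a, dtype=np.float64))
    db = _dist_matrix(np.asarray(b, dtype=np.float64))
    diff = squareform(da - db, checks=False)
    return float(np.sqrt(np.dot(diff, diff) / _pair_count(n)))


def partial_drmsd(B: Backbone, prefix: Conformation) -> float:
    """dRMSD restricted to the first k assigned positions (denominator k(k-1)/2).

    Used by chain growth, which scores partially built conformations.
    """
    k = len(prefix)
    if k < 2:
        raise ValueError("partial dRMSD needs a prefix of length >= 2")
    if k > len(B):
        raise ValueError("prefix longer than backbone")
    return drmsd_coords(B.coords[:k], prefix.coords_angstrom())


class DistanceCache:
    """Pairwise-distance state for one (backbone, conformation) pair.

    Holds the fixed reference distance matrix, the current conformation's
    distance matrix (in Å) and the running squared-error sum.  ``simulate``
    prices a move without mutating state; ``commit`` applies it.  The running
    sum is refreshed from the matrix every few hundred commits so it agrees
    with a from-scratch recomputation to 1e-9 relative over arbitrarily long
    move sequences.
    """

    def __init__(self, B: Backbone, C: Conformation):
        if len(B) != len(C):
            raise ValueError("backbone and conformation lengths differ")
        self.n = len(B)
        self.ref_dists = _dist_matrix(B.coords)
        self.scale = C.lattice.scale
        self.coords = C.coords_angstrom()
        self.conf_dists = _dist_matrix(self.coords)
        self._err = (self.conf_dists - self.ref_dists) ** 2
        self.sq_error_sum = float(np.triu(self._err, 1).sum())
        self._commits = 0

    # -- objective values ---------------------------------------------------

    def drmsd(self) -> float:
        return float(np.sqrt(self.sq_error_sum / _pair_count(self.n)))

    def sq_sum_from_scratch(self) -> float:
        """O(n^2) recomputation of the squared-error sum (oracle/refresh path)."""
        err = (self.conf_dists - self.ref_dists) ** 2
        return float(np.triu(err, 1).sum())

    # -- move pricing -------------------------------------------------------

    def simulate(self, moved: np.ndarray, new_points_ang: np.ndarray) -> float:
        """Squared-error sum after moving residues ``moved`` to ``new_points_ang``.

        ``moved`` is an index array, ``new_points_ang`` the proposed Å
        coordinates for exactly those residues.  Cost O(|moved| * n); the
        cache is not modified.  Returns the proposed sq_error_sum.
        """
        moved = np.asarray(moved, dtype=np.intp)
        k = len(moved)
        if k == 0:
            return self.sq_error_sum
        new_coords = self.coords.copy()
        new_coords[moved] = new_points_ang
        # distances from each moved residue to all residues, after the move
        d_new = cdist(new_coords[moved], new_coords)
        err_new = (d_new - self.ref_dists[moved]) ** 2
        err_old = self._err[moved]
        # moved-row pairs: each moved x unmoved pair appears once, each
        # moved x moved pair twice; self pairs contribute zero either way
        mm_new = err_new[:, moved]
        mm_old = err_old[:, moved]
        delta = (err_new.sum() - err_old.sum()) - 0.5 * (mm_new.sum() - mm_old.sum())
        return self.sq_error_sum + float(delta)

    def simulate_drmsd(self, moved, new_points_ang) -> float:
        return float(np.sqrt(self.simulate(moved, new_points_ang) / _pair_count(self.n)))

    def commit(self, moved: np.ndarray, new_points_ang: np.ndarray) -> None:
        """Apply a previously simulated move and update all cached state."""
        moved = np.asarray(moved, dtype=np.intp)
        if len(moved) == 0:
            return
        self.sq_error_sum = self.simulate(moved, new_points_ang)
        self.coords[moved] = new_points_ang
        d_new = cdist(self.coords[moved], self.coords)
        self.conf_dists[moved, :] = d_new
        self.conf_dists[:, moved] = d_new.T
        err_new = (d_new - self.ref_dists[moved]) ** 2
        self._err[moved, :] = err_new
        self._err[:, moved] = err_new.T
        self._commits += 1
        if self._commits % _REFRESH_EVERY == 0:
            self.sq_error_sum = self.sq_sum_from_scratch()


def simulate_delta(cache: DistanceCache, moved, new_points_lattice, lattice=None) -> float:
    """dRMSD of the proposed conformation, without committing the move.

    ``new_points_lattice`` are integer lattice coordinates for the residues
    in ``moved``; they are scaled to Å with the cache's lattice scale.  The
    caller is responsible for chain/self-avoidance validity of the proposal.
    """
    moved = np.asarray(moved, dtype=np.intp)
    if len(moved) == 0:
        return cache.drmsd()
    pts = np.asarray(new_points_lattice, dtype=np.float64) * cache.scale
    return cache.simulate_drmsd(moved, pts)
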