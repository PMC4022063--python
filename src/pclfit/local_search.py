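"""Constraint-based local search for protein chain lattice fitting.

Starting from the chain-growth conformation, each iteration picks one of two
move operators at random, generates that operator's neighborhood around
randomly chosen non-tabu positions, prices every candidate without
committing it, and accepts the best candidate *including the incumbent* —
so the objective trace is monotone non-increasing.  Recently moved
positions become tabu for a fixed tenure.  When the global best has not
improved for ``stagnation`` consecutive iterations, the jump-move size
grows by one and the stagnation threshold is multiplied by ``factor``; both
reset on the next improvement.

Move operators
--------------
*Jump*: a selected residue is re-placed at any free lattice point adjacent
to both of its chain neighbors (for a terminal residue: adjacent to its
single neighbor).  With move size m > 1, m residues are relocated
sequentially in index order, each relocation conditioned on the previous.

*Pull*: a residue relocates to a free point L adjacent to one chain
neighbor (the anchor); if the chain bond on the other side breaks, a free
corner point adjacent to both L and the residue's old position takes the
adjacent residue, and the remaining tail follows the vacated trail two
steps behind until the chain constraint is restored.  End residues may also
drag the whole chain reptation-style.  Every candidate is validated before
being returned from the public wrappers; inside the search a validity
assertion runs on each accepted move.

Candidate pricing is batched: all proposals of an iteration are evaluated
in one vectorized pass (from-scratch for modest chain lengths, through the
incremental :class:`~pclfit.metrics.DistanceCache` otherwise).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .chain_growth import chain_growth_init
from .lattice import LatticeModel
from .metrics import IMPROVE_EPS, DistanceCache, _pair_count
from .structures import Backbone, Conformation, validate

#: hard cap on jump-move combination explosion per iteration
MAX_JUMP_COMBOS = 512

#: move size never exceeds min(this, n - 2)
MAX_MOVE_SIZE = 5

#: batch from-scratch pricing while m * n^2 stays below this
_BATCH_FLOPS = 4_000_000


@dataclass
class SearchConfig:
    """Tunable parameters of the local search."""

    move_size_init: int = 1
    stagnation_init: int = 1000
    factor: float = 1.5
    tabu_tenure: int | None = None  # default: max(5, n // 10)
    max_iterations: int = 10_000
    time_limit: float | None = None  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.move_size_init < 1:
            raise ValueError("move_size_init must be >= 1")
        if self.factor <= 1:
            raise ValueError("factor must be > 1")
        if self.stagnation_init < 1:
            raise ValueError("stagnation_init must be >= 1")
        if self.tabu_tenure is not None and self.tabu_tenure < 0:
            raise ValueError("tabu_tenure must be >= 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    def tenure_for(self, n: int) -> int:
        return self.tabu_tenure if self.tabu_tenure is not None else max(5, n // 10)


@dataclass
class SearchResult:
    """Outcome of one search run."""

    best: Conformation
    best_objective: float
    trace: list[tuple[int, float]] = field(repr=False)
    iterations: int = 0
    seed: int = 0
    initial_objective: float = float("nan")


# --------------------------------------------------------------------------
# move generation (pure tuple arithmetic; the hot path of the search)

Point = tuple[int, int, int]
Move = dict[int, Point]  # residue index -> new lattice point


def _pull_candidates(
    points: list[Point], occupied, i: int, lat: LatticeModel, bound: int
) -> list[Move]:
    n = len(points)
    basis = lat.basis_tuples
    basis_set = lat.basis_set
    out: list[Move] = []
    seen: set = set()
    p_i = points[i]

    def free(q: Point) -> bool:
        return (
            -bound <= q[0] <= bound
            and -bound <= q[1] <= bound
            and -bound <= q[2] <= bound
            and q not in occupied
        )

    def adj(a: Point, b: Point) -> bool:
        return (b[0] - a[0], b[1] - a[1], b[2] - a[2]) in basis_set

    def emit(moves: Move) -> None:
        key = tuple(sorted(moves.items()))
        if key not in seen:
            seen.add(key)
            out.append(moves)

    for anchor_side in (1, -1):
        a_idx = i + anchor_side
        if not (0 <= a_idx < n):
            # i is the chain end on this side: drag the whole chain
            for v in basis:
                L = (p_i[0] + v[0], p_i[1] + v[1], p_i[2] + v[2])
                if not free(L):
                    continue
                moves: Move = {i: L}
                prev_old = p_i
                j = i - anchor_side
                while 0 <= j < n:
                    if adj(moves[j + anchor_side], points[j]):
                        break  # chain restored
                    moves[j], prev_old = prev_old, points[j]
                    j -= anchor_side
                emit(moves)
            continue
        anchor = points[a_idx]
        pull_dir = -anchor_side
        j_next = i + pull_dir
        for v in basis:
            L = (anchor[0] + v[0], anchor[1] + v[1], anchor[2] + v[2])
            if L == p_i or not free(L):
                continue
            if not (0 <= j_next < n):
                emit({i: L})  # terminal residue: plain relocation
                continue
            if adj(L, points[j_next]):
                emit({i: L})  # bond to j_next survives
                continue
            if adj(L, p_i):
                # L touches the vacated position: the tail can follow the
                # trail one step behind (possible on FCC, never on cubic)
                moves = {i: L}
                j = j_next
                while 0 <= j < n:
                    if adj(moves[j - pull_dir], points[j]):
                        break
                    moves[j] = points[j - pull_dir]
                    j += pull_dir
                emit(moves)
            # corner point adjacent to both L and the vacated p_i
            for w in basis:
                Cpt = (L[0] + w[0], L[1] + w[1], L[2] + w[2])
                if not adj(p_i, Cpt):
                    continue
                if Cpt == points[j_next]:
                    emit({i: L})
                    continue
                if not free(Cpt):
                    continue
                moves = {i: L, j_next: Cpt}
                # tail follows the vacated trail two steps behind
                j = j_next + pull_dir
                while 0 <= j < n:
                    if adj(moves[j - pull_dir], points[j]):
                        break
                    moves[j] = points[j - 2 * pull_dir]
                    j += pull_dir
                emit(moves)
    return out


def _jump_options(
    points: list[Point], occupied, k: int, lat: LatticeModel, bound: int
) -> list[Point]:
    """Free relocation targets for residue k consistent with its chain neighbors."""
    n = len(points)
    basis = lat.basis_tuples
    basis_set = lat.basis_set
    cur = points[k]
    opts: list[Point] = []
    if 0 < k < n - 1:
        a, b = points[k - 1], points[k + 1]
        for v in basis:
            q = (a[0] + v[0], a[1] + v[1], a[2] + v[2])
            if (
                q != cur
                and (b[0] - q[0], b[1] - q[1], b[2] - q[2]) in basis_set
                and -bound <= q[0] <= bound
                and -bound <= q[1] <= bound
                and -bound <= q[2] <= bound
                and q not in occupied
            ):
                opts.append(q)
    else:
        ref = points[1] if k == 0 else points[n - 2]
        for v in basis:
            q = (ref[0] + v[0], ref[1] + v[1], ref[2] + v[2])
            if (
                q != cur
                and -bound <= q[0] <= bound
                and -bound <= q[1] <= bound
                and -bound <= q[2] <= bound
                and q not in occupied
            ):
                opts.append(q)
    return opts


def _jump_candidates(
    points: list[Point], occupied, indices, lat: LatticeModel, bound: int
) -> list[Move]:
    indices = sorted(int(k) for k in indices)
    if len(indices) == 1:
        k = indices[0]
        return [{k: q} for q in _jump_options(points, occupied, k, lat, bound)]
    # sequential per-index relocation, each conditioned on the previous
    out: list[Move] = []
    work = list(points)
    occ = dict(occupied) if isinstance(occupied, dict) else {p: 1 for p in occupied}

    def rec(pos: int, moves: Move) -> None:
        if len(out) >= MAX_JUMP_COMBOS:
            return
        if pos == len(indices):
            if moves:
                out.append(dict(moves))
            return
        k = indices[pos]
        rec(pos + 1, moves)  # leave residue k in place
        for q in _jump_options(work, occ, k, lat, bound):
            old = work[k]
            del occ[old]
            occ[q] = k
            work[k] = q
            moves[k] = q
            rec(pos + 1, moves)
            del moves[k]
            del occ[q]
            occ[old] = k
            work[k] = old

    rec(0, {})
    return out


def _apply_move(points: np.ndarray, move: Move) -> np.ndarray:
    new = points.copy()
    for k, q in move.items():
        new[k] = q
    return new


def pull_move_neighbors(C: Conformation, i: int) -> list[Conformation]:
    """All valid conformations reachable by one pull move at residue ``i``."""
    n = len(C)
    if not (0 <= i < n):
        raise IndexError(f"residue index {i} out of range for n={n}")
    pts = [tuple(p) for p in C.points.tolist()]
    moves = _pull_candidates(pts, set(pts), i, C.lattice, n)
    out = []
    for mv in moves:
        cand = Conformation(_apply_move(C.points, mv), C.lattice)
        if not validate(cand) and cand != C:
            out.append(cand)
    return out


def jump_move_neighbors(
    C: Conformation, indices, move_size: int | None = None
) -> list[Conformation]:
    """All valid conformations from jump-relocating the given residues."""
    indices = [int(k) for k in np.atleast_1d(indices)]
    if move_size is None:
        move_size = len(indices)
    if move_size < 1:
        raise ValueError("move_size must be >= 1")
    if len(indices) != move_size:
        raise ValueError("need exactly move_size indices")
    n = len(C)
    for k in indices:
        if not (0 <= k < n):
            raise IndexError(f"residue index {k} out of range for n={n}")
    pts = [tuple(p) for p in C.points.tolist()]
    occ = {p: k for k, p in enumerate(pts)}
    moves = _jump_candidates(pts, occ, indices, C.lattice, n)
    out = []
    for mv in moves:
        cand = Conformation(_apply_move(C.points, mv), C.lattice)
        if not validate(cand) and cand != C:
            out.append(cand)
    return out


# --------------------------------------------------------------------------
# batched candidate pricing

def _batch_coords(base: np.ndarray, moves: list[Move]) -> np.ndarray:
    """Stack candidate coordinate sets: (m, n, 3) lattice-unit floats."""
    coords = np.repeat(base[None, :, :], len(moves), axis=0)
    for t, mv in enumerate(moves):
        for k, q in mv.items():
            coords[t, k] = q
    return coords


def _batch_sq_sums(ref_dists: np.ndarray, coords_ang: np.ndarray) -> np.ndarray:
    """Squared-error sums of each candidate against the reference distances."""
    diff = coords_ang[:, :, None, :] - coords_ang[:, None, :, :]
    d = np.sqrt(np.einsum("mijk,mijk->mij", diff, diff))
    err = (d - ref_dists) ** 2
    return err.sum(axis=(1, 2)) / 2.0


def _batch_energies(
    pot: np.ndarray, coords_lattice: np.ndarray, contact_sqrdist: int
) -> np.ndarray:
    """Contact energies of each candidate under a sequence-potential matrix."""
    diff = coords_lattice[:, :, None, :] - coords_lattice[:, None, :, :]
    sq = np.einsum("mijk,mijk->mij", diff, diff)
    contacts = sq == contact_sqrdist
    n = coords_lattice.shape[1]
    idx = np.arange(n - 1)
    contacts[:, idx, idx + 1] = False
    contacts[:, idx + 1, idx] = False
    return (contacts * pot).sum(axis=(1, 2)) / 2.0


# --------------------------------------------------------------------------
# the search

def pclf_search(
    B: Backbone,
    lat: LatticeModel,
    cfg: SearchConfig | None = None,
    objective=None,
    record_hook=None,
    start: Conformation | None = None,
) -> SearchResult:
    """Fit backbone ``B`` onto lattice ``lat`` by tabu local search.

    ``objective`` selects what the search minimizes: None for the standard
    dRMSD fit, an :class:`~pclfit.energy.EnergyModel` (or its name) for
    energy-guided sampling, or any callable ``Conformation -> float``.
    ``record_hook(iteration, conformation, drmsd)`` is called after every
    iteration's acceptance decision.  Identical seeds give identical runs.
    """
    cfg = cfg or SearchConfig()
    n = len(B)
    rng = np.random.default_rng(cfg.seed)
    C0 = start.copy() if start is not None else chain_growth_init(B, lat)
    points_arr = C0.points.copy()
    points: list[Point] = [tuple(p) for p in points_arr.tolist()]
    occupied: dict[Point, int] = {p: k for k, p in enumerate(points)}
    cache = DistanceCache(B, Conformation(points_arr, lat))
    pairs = _pair_count(n)

    # objective plumbing: 'drmsd' uses squared sums; energy uses a
    # sequence-potential matrix; anything else is a per-candidate callable
    pot = None
    generic = None
    if objective is None:
        kind = "drmsd"
        cur_obj = cache.sq_error_sum
    else:
        from .energy import EnergyModel, load_energy_model

        model = objective
        if isinstance(model, str) and model != "drmsd":
            model = load_energy_model(model)
        if isinstance(model, EnergyModel):
            kind = "energy"
            pot = model.sequence_potential(B.sequence)
            cur_obj = float(
                _batch_energies(
                    pot, points_arr[None].astype(np.float64), lat.contact_sqrdist
                )[0]
            )
        elif model == "drmsd":
            kind = "drmsd"
            cur_obj = cache.sq_error_sum
        else:
            kind = "generic"
            generic = model
            cur_obj = float(generic(Conformation(points_arr, lat)))

    def report(v: float) -> float:
        return float(np.sqrt(max(v, 0.0) / pairs)) if kind == "drmsd" else v

    # one pricing currency per run so acceptance comparisons are exact
    batch_ok = len(points) ** 2 * 64 <= _BATCH_FLOPS

    def price(moves: list[Move]) -> np.ndarray:
        if kind == "drmsd":
            if batch_ok:
                coords = _batch_coords(points_arr.astype(np.float64), moves)
                return _batch_sq_sums(cache.ref_dists, coords * lat.scale)
            vals = np.empty(len(moves))
            for t, mv in enumerate(moves):
                idx = np.fromiter(mv, dtype=np.intp)
                pts = np.array([mv[k] for k in mv], dtype=np.float64)
                vals[t] = cache.simulate(idx, pts * lat.scale)
            return vals
        if kind == "energy":
            coords = _batch_coords(points_arr.astype(np.float64), moves)
            return _batch_energies(pot, coords, lat.contact_sqrdist)
        return np.array(
            [float(generic(Conformation(_apply_move(points_arr, mv), lat)))
             for mv in moves]
        )

    tenure = cfg.tenure_for(n)
    tabu_until = np.zeros(n, dtype=np.int64)
    move_size = cfg.move_size_init
    move_size_cap = max(1, min(MAX_MOVE_SIZE, n - 2))
    stagnation = float(cfg.stagnation_init)
    since_improve = 0
    best_points = points_arr.copy()
    best_obj = cur_obj
    trace: list[tuple[int, float]] = [(0, report(cur_obj))]

    def hook_drmsd() -> float:
        # for the dRMSD objective report the accepted objective itself so the
        # recorded column is exactly the monotone trace; otherwise the cache
        return report(cur_obj) if kind == "drmsd" else cache.drmsd()

    if record_hook is not None:
        record_hook(0, Conformation(points_arr.copy(), lat), hook_drmsd())

    deadline = None if cfg.time_limit is None else time.monotonic() + cfg.time_limit
    iterations_done = 0
    for it in range(1, cfg.max_iterations + 1):
        if deadline is not None and time.monotonic() >= deadline:
            break
        iterations_done = it
        eligible = np.nonzero(tabu_until < it)[0]
        improved = False
        if len(eligible):
            if rng.random() < 0.5:  # pull
                i = int(eligible[rng.integers(len(eligible))])
                cands = _pull_candidates(points, occupied, i, lat, n)
            else:  # jump: a contiguous run of move_size positions starting
                # at a random eligible index (the reoptimized substructure)
                start = int(eligible[rng.integers(len(eligible))])
                m = min(move_size, n - start)
                sel = range(start, start + m)
                cands = _jump_candidates(points, occupied, sel, lat, n)
            if cands:
                vals = price(cands)
                t_best = int(np.argmin(vals))
                if vals[t_best] < cur_obj - IMPROVE_EPS:
                    mv = cands[t_best]
                    idx = np.fromiter(sorted(mv), dtype=np.intp)
                    new_pts = np.array([mv[k] for k in sorted(mv)], dtype=np.int64)
                    cand_arr = points_arr.copy()
                    cand_arr[idx] = new_pts
                    if validate(Conformation(cand_arr, lat)):
                        raise AssertionError(
                            "move generator produced an invalid conformation"
                        )
                    cache.commit(idx, new_pts.astype(np.float64) * lat.scale)
                    for k in idx.tolist():
                        del occupied[points[k]]
                    for k, q in zip(idx.tolist(), map(tuple, new_pts.tolist())):
                        occupied[q] = k
                        points[k] = q
                    points_arr = cand_arr
                    cur_obj = float(vals[t_best])
                    tabu_until[idx] = it + tenure
                    if cur_obj < best_obj - IMPROVE_EPS:
                        best_obj = cur_obj
                        best_points = points_arr.copy()
                        improved = True
        trace.append((it, report(cur_obj)))
        if record_hook is not None:
            record_hook(it, Conformation(points_arr.copy(), lat), hook_drmsd())
        if improved:
            move_size = cfg.move_size_init
            stagnation = float(cfg.stagnation_init)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= stagnation:
                move_size = min(move_size + 1, move_size_cap)
                stagnation *= cfg.factor
                since_improve = 0

    return SearchResult(
        best=Conformation(best_points, lat),
        best_objective=report(best_obj),
        trace=trace,
        iterations=iterations_done,
        seed=cfg.seed,
        initial_objective=trace[0][1],
    )


# --------------------------------------------------------------------------
# exhaustive oracle

_BRUTE_GUARD = {"cubic": 8, "fcc": 6}


def brute_force_fit(B: Backbone, lat: LatticeModel) -> tuple[Conformation, float]:
    """Global optimum by enumerating all self-avoiding walks (tiny n only).

    The first step is fixed to basis vector 0 — dRMSD is isometry-invariant
    and the lattice point group acts transitively on the basis, so no
    optimum is lost.  Guarded to n <= 8 (cubic) / n <= 6 (FCC).
    """
    n = len(B)
    guard = _BRUTE_GUARD[lat.name]
    if n > guard:
        raise ValueError(f"brute force guarded to n <= {guard} on {lat.name}")
    from scipy.spatial.distance import cdist

    ref = cdist(B.coords, B.coords)
    basis = lat.basis
    scale = lat.scale
    points = np.zeros((n, 3), dtype=np.int64)
    points[1] = basis[0]
    best_sq = np.inf
    best_pts: np.ndarray | None = None
    sq_at = np.zeros(n + 1)
    d01 = float(np.linalg.norm(basis[0].astype(float))) * scale
    sq_at[2] = (d01 - ref[0, 1]) ** 2

    def rec(k: int) -> None:
        nonlocal best_sq, best_pts
        if sq_at[k] >= best_sq:
            return
        if k == n:
            best_sq = sq_at[k]
            best_pts = points.copy()
            return
        prefix = points[:k].astype(np.float64) * scale
        occupied = {tuple(p) for p in points[:k].tolist()}
        for v in basis:
            q = points[k - 1] + v
            if tuple(q.tolist()) in occupied:
                continue
            d = np.linalg.norm(prefix - q.astype(np.float64) * scale, axis=1)
            add = ((d - ref[k, :k]) ** 2).sum()
            sq_at[k + 1] = sq_at[k] + add
            points[k] = q
            rec(k + 1)

    if n == 2:
        best_sq = sq_at[2]
        best_pts = points[:2].copy()
    else:
        rec(2)
    assert best_pts is not None
    return (
        Conformation(best_pts, lat),
        float(np.sqrt(best_sq / _pair_count(n))),
    )
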