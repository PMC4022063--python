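"""Greedy chain-growth initialization with backtracking.

The first residue is pinned at the origin.  Each subsequent residue is
placed at the unoccupied neighbor of the previous one that minimizes the
partial dRMSD of the placed prefix; ties (within 1e-12 absolute on the
squared-error cost) are broken by the canonical basis-vector order, acting
as a FIFO queue of directions.  When no free neighbor exists the algorithm
backtracks depth-first, remembering which directions were already tried at
each position along the current partial path so none is retried.  The whole
procedure is deterministic.

Backtracking is bounded by a node-visit cap (default 10^6); past the cap the
deepest prefix reached is extended by the cheapest free direction without
further backtracking.  On backbones that are exact scaled lattice walks the
greedy extension is lossless: a zero-cost direction exists at every step, so
the returned conformation has dRMSD 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .lattice import LatticeModel
from .structures import Backbone, Conformation

#: absolute tolerance below which partial costs count as tied
TIE_ATOL = 1e-12

DEFAULT_NODE_CAP = 1_000_000


class ChainGrowthError(RuntimeError):
    """Raised when backtracking exhausts every alternative."""


def _fifo_order(costs: np.ndarray) -> np.ndarray:
    """Indices sorted by cost, with groups tied within 1e-12 kept in index order."""
    order = np.argsort(costs, kind="stable")
    out: list[int] = []
    i = 0
    while i < len(order):
        j = i + 1
        anchor = costs[order[i]]
        while j < len(order) and costs[order[j]] <= anchor + TIE_ATOL:
            j += 1
        out.extend(sorted(order[i:j].tolist()))
        i = j
    return np.asarray(out, dtype=np.intp)


def _extension_costs(
    B: Backbone, points: np.ndarray, k: int, lat: LatticeModel
) -> tuple[np.ndarray, np.ndarray]:
    """(costs, free_mask) over all basis directions for placing position k.

    Cost is the squared-error increase Σ_j (dist(q, p_j) − dist(b_k, b_j))²
    over the placed prefix j < k; occupied targets get cost +inf.
    """
    cand = points[k - 1] + lat.basis
    occupied = {tuple(p) for p in points[:k].tolist()}
    free = np.fromiter(
        (tuple(c) not in occupied for c in cand.tolist()), bool, len(cand)
    )
    ref_row = np.linalg.norm(B.coords[:k] - B.coords[k], axis=1)
    d = cdist(cand.astype(np.float64) * lat.scale, points[:k].astype(np.float64) * lat.scale)
    costs = ((d - ref_row) ** 2).sum(axis=1)
    costs[~free] = np.inf
    return costs, free


def select_direction(
    B: Backbone,
    prefix: Conformation,
    tried: set[int] | frozenset[int] = frozenset(),
) -> int | None:
    """Basis index whose extension minimizes the partial dRMSD, or None.

    Considers directions not in ``tried`` whose target point is free; exact
    ties resolve to the smallest basis index (FIFO).  None signals a dead
    end.
    """
    k = len(prefix)
    if k < 1 or k >= len(B):
        raise ValueError("prefix length must be in [1, n)")
    costs, free = _extension_costs(B, prefix.points, k, prefix.lattice)
    for bi in tried:
        free[bi] = False
        costs[bi] = np.inf
    if not free.any():
        return None
    order = _fifo_order(costs)
    return int(order[0])


def chain_growth_init(
    B: Backbone,
    lat: LatticeModel,
    node_cap: int = DEFAULT_NODE_CAP,
    stats: dict | None = None,
) -> Conformation:
    """Grow a valid conformation for backbone ``B`` on lattice ``lat``.

    Greedy in partial dRMSD with FIFO tie-breaks, depth-first backtracking
    on dead ends, and a node-visit cap after which growth proceeds greedily
    without backtracking.  Pass a dict as ``stats`` to collect the node
    visit and backtrack counts.
    """
    n = len(B)
    if n < 2:
        raise ValueError("backbone must have at least 2 residues")
    points = np.zeros((n, 3), dtype=np.int64)
    occupied: dict[tuple[int, int, int], int] = {(0, 0, 0): 0}
    # order_stack[k-1]: candidate directions for position k, best first;
    # cursor_stack[k-1]: how many of them were already tried on this path
    order_stack: list[np.ndarray] = []
    cursor_stack: list[int] = []
    depth = 1
    visits = 0
    backtracks = 0
    capped = False

    while depth < n:
        if len(order_stack) < depth:
            costs, free = _extension_costs(B, points, depth, lat)
            order = _fifo_order(costs)[: int(free.sum())]
            order_stack.append(order)
            cursor_stack.append(0)
        order = order_stack[depth - 1]
        cur = cursor_stack[depth - 1]
        if cur >= len(order):
            if depth == 1 or capped:
                raise ChainGrowthError(
                    f"chain growth exhausted all alternatives at depth {depth}"
                )
            order_stack.pop()
            cursor_stack.pop()
            depth -= 1
            backtracks += 1
            del occupied[tuple(points[depth].tolist())]
            continue
        cursor_stack[depth - 1] = len(order) if capped else cur + 1
        q = points[depth - 1] + lat.basis[int(order[cur])]
        points[depth] = q
        occupied[tuple(q.tolist())] = depth
        depth += 1
        visits += 1
        if visits >= node_cap:
            capped = True
    if stats is not None:
        stats.update(visits=visits, backtracks=backtracks, capped=capped)
    return Conformation(points, lat)
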