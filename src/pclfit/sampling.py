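"""Conformation-space sampling and energy/dRMSD correlation analysis.

Five samplers generate candidate structures per protein and lattice:

* ``pclf`` — the local search minimizing dRMSD itself;
* ``guided-hp-basic`` / ``guided-mj`` / ``guided-bre`` — the same search
  with the objective replaced by the named contact energy (dRMSD is still
  recorded for every accepted candidate, it just no longer guides);
* ``random-walk`` — random chain-growth initialization, then a uniformly
  random valid neighbor accepted every iteration, with no objective at all.

Each sampler emits one record per iteration: the accepted candidate's dRMSD
and its energy under all three models.  Per protein, the Spearman rank
correlation between an energy column and the dRMSD column measures whether
minimizing that energy would drive a search toward the native structure; a
strong positive correlation is what an effective energy model would show.
Per-protein coefficients are then binned into the four ranges >0, >0.5,
<=0, <-0.5 (the first and third partition the proteins; the others are
their strict subsets), and minimum-dRMSD tables compare how deep each
sampler digs relative to the random walk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chain_growth import ChainGrowthError
from .energy import MODEL_NAMES, load_energy_model, total_energy
from .lattice import LatticeModel
from .local_search import (
    SearchConfig,
    _jump_candidates,
    _pull_candidates,
    pclf_search,
)
from .metrics import drmsd
from .structures import Backbone, Conformation, validate

SAMPLER_MODES = ("pclf", "guided-hp-basic", "guided-mj", "guided-bre", "random-walk")

_ENERGY_COLS = ("e_hp", "e_mj", "e_bre")
_COL_FOR_MODEL = {"hp-basic": "e_hp", "mj": "e_mj", "bre": "e_bre"}


@dataclass
class SampleTrace:
    """Per-iteration records from one sampler run on one protein."""

    protein_id: str
    lattice: str
    sampler: str
    records: list[tuple[int, float, float, float, float]] = field(repr=False)
    seed: int = 0

    def column(self, name: str) -> np.ndarray:
        idx = {"iteration": 0, "drmsd": 1, "e_hp": 2, "e_mj": 3, "e_bre": 4}[name]
        return np.array([r[idx] for r in self.records], dtype=np.float64)

    def min_drmsd(self) -> float:
        return float(self.column("drmsd").min()) if self.records else float("nan")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "drmsd", "e_hp", "e_mj", "e_bre"])
            w.writerows(self.records)

    @classmethod
    def from_csv(cls, path, protein_id: str = "", lattice: str = "",
                 sampler: str = "", seed: int = 0) -> "SampleTrace":
        recs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                recs.append((int(float(row["iteration"])), float(row["drmsd"]),
                             float(row["e_hp"]), float(row["e_mj"]),
                             float(row["e_bre"])))
        pid = protein_id or Path(path).stem
        return cls(pid, lattice, sampler, recs, seed)


def _random_chain_growth(
    B: Backbone, lat: LatticeModel, rng: np.random.Generator, max_restarts: int = 200
) -> Conformation:
    """Self-avoiding walk grown by uniformly random free directions.

    Restarts from scratch on dead ends; gives the random-walk sampler a
    valid but unbiased starting structure.
    """
    n = len(B)
    for _ in range(max_restarts):
        points = np.zeros((n, 3), dtype=np.int64)
        occupied = {(0, 0, 0)}
        ok = True
        for k in range(1, n):
            cands = points[k - 1] + lat.basis
            free = [q for q in map(tuple, cands.tolist()) if q not in occupied]
            if not free:
                ok = False
                break
            q = free[rng.integers(len(free))]
            points[k] = q
            occupied.add(q)
        if ok:
            return Conformation(points, lat)
    raise ChainGrowthError("random chain growth kept dead-ending")


def run_sampler(
    B: Backbone,
    lat: LatticeModel,
    mode: str,
    n_samples: int = 10_000,
    cfg: SearchConfig | None = None,
) -> SampleTrace:
    """Run one sampler and collect (iteration, dRMSD, e_hp, e_mj, e_bre) records."""
    if mode not in SAMPLER_MODES:
        raise ValueError(f"unknown sampler mode {mode!r}; choose from {SAMPLER_MODES}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = cfg or SearchConfig()
    models = {name: load_energy_model(name) for name in MODEL_NAMES}
    pots = {name: m.sequence_potential(B.sequence) for name, m in models.items()}

    def energies(C: Conformation) -> tuple[float, float, float]:
        from .energy import contact_matrix

        mat = contact_matrix(C)
        return tuple(float(pots[name][mat].sum() / 2.0) for name in MODEL_NAMES)

    records: list[tuple[int, float, float, float, float]] = []

    if mode == "random-walk":
        rng = np.random.default_rng(cfg.seed)
        n = len(B)
        C = _random_chain_growth(B, lat, rng)
        points_arr = C.points
        points = [tuple(p) for p in points_arr.tolist()]
        occupied = {p: k for k, p in enumerate(points)}
        attempts = 0
        while len(records) < n_samples and attempts < 20 * n_samples:
            attempts += 1
            i = int(rng.integers(n))
            if rng.random() < 0.5:
                cands = _pull_candidates(points, occupied, i, lat, n)
            else:
                cands = _jump_candidates(points, occupied, [i], lat, n)
            if not cands:
                continue
            move = cands[rng.integers(len(cands))]
            for k, q in move.items():
                del occupied[points[k]]
                points[k] = q
                points_arr[k] = q
                occupied[q] = k
            C = Conformation(points_arr.copy(), lat)
            e = energies(C)
            records.append((len(records), drmsd(B, C), *e))
        return SampleTrace(B.id, lat.name, mode, records, cfg.seed)

    objective = None if mode == "pclf" else models[mode.removeprefix("guided-")]

    def hook(it: int, C: Conformation, d: float) -> None:
        if it == 0:
            return
        records.append((len(records), d, *energies(C)))

    run_cfg = SearchConfig(
        move_size_init=cfg.move_size_init,
        stagnation_init=cfg.stagnation_init,
        factor=cfg.factor,
        tabu_tenure=cfg.tabu_tenure,
        max_iterations=n_samples,
        time_limit=cfg.time_limit,
        seed=cfg.seed,
    )
    pclf_search(B, lat, run_cfg, objective=objective, record_hook=hook)
    return SampleTrace(B.id, lat.name, mode, records, cfg.seed)


# --------------------------------------------------------------------------
# correlation analysis

def spearman(trace: SampleTrace, energy_name: str, with_p: bool = False):
    """Spearman rank correlation between one energy column and dRMSD.

    Average ranks on ties.  Returns NaN when either column is constant
    (undefined correlation; such proteins are excluded from binning).
    """
    col = _COL_FOR_MODEL.get(energy_name, energy_name)
    if col not in _ENERGY_COLS:
        raise KeyError(f"unknown energy column {energy_name!r}")
    e = trace.column(col)
    d = trace.column("drmsd")
    if len(e) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    if np.ptp(e) == 0 or np.ptp(d) == 0:
        return (float("nan"), float("nan")) if with_p else float("nan")
    rho, p = stats.spearmanr(e, d)
    return (float(rho), float(p)) if with_p else float(rho)


BIN_LABELS = (">0", ">0.5", "<=0", "<-0.5")


def correlation_bins(rhos) -> dict[str, float]:
    """Percentage of proteins per correlation range.

    ``>0`` and ``<=0`` partition the proteins (rho = 0 counts as <=0);
    ``>0.5`` and ``<-0.5`` are subsets of the respective halves.  NaN
    (undefined) coefficients are excluded before computing percentages.
    """
    arr = np.asarray(list(rhos), dtype=np.float64)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined correlation coefficients to bin")
    n = arr.size
    return {
        ">0": 100.0 * (arr > 0).sum() / n,
        ">0.5": 100.0 * (arr > 0.5).sum() / n,
        "<=0": 100.0 * (arr <= 0).sum() / n,
        "<-0.5": 100.0 * (arr < -0.5).sum() / n,
    }


def correlation_table(traces: list[SampleTrace]) -> pd.DataFrame:
    """Per-(sampler, energy) bin table over a set of per-protein traces."""
    rows = []
    for sampler in sorted({t.sampler for t in traces}):
        group = [t for t in traces if t.sampler == sampler]
        for name in MODEL_NAMES:
            rhos = [spearman(t, name) for t in group if len(t.records) >= 3]
            try:
                bins = correlation_bins(rhos)
            except ValueError:
                continue
            rows.append({"sampler": sampler, "energy": name, **bins})
    return pd.DataFrame(rows)


def min_drmsd_summary(traces: list[SampleTrace]) -> pd.DataFrame:
    """Tidy per-(protein, sampler) minimum-dRMSD table.

    One row per protein, one column per sampler; ready for scattering each
    sampler's minima against the random walk's.  Proteins with empty traces
    are dropped.
    """
    rows = [
        {
            "protein_id": t.protein_id,
            "lattice": t.lattice,
            "sampler": t.sampler,
            "min_drmsd": t.min_drmsd(),
        }
        for t in traces
        if t.records
    ]
    if not rows:
        return pd.DataFrame(columns=["protein_id", "lattice"])
    tidy = pd.DataFrame(rows)
    return (
        tidy.pivot_table(
            index=["protein_id", "lattice"], columns="sampler", values="min_drmsd"
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
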