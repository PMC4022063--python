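# pclfit — protein chain lattice fitting and contact-energy assessment

`pclfit` answers two questions about simplified lattice models of protein
structure, for people building or evaluating lattice-based structure
prediction methods:

1. **How closely can a discrete lattice represent a real backbone?**
   Given the Cα trace of a native chain, find the self-avoiding lattice
   conformation (cubic or face-centered cubic) that minimizes the
   distance-matrix RMSD to it.
2. **Do contact-based energy models actually guide a search toward the
   native structure?**  Sample conformation space in several regimes and
   measure the rank correlation between contact energies (HP,
   Miyazawa–Jernigan, an empirical contact potential) and dRMSD.

## The model

A conformation is a sequence of integer lattice points `C = p_1 … p_n`
with three constraints: every consecutive pair differs by a lattice basis
vector (*chain*), no point repeats (*self-avoiding*), and all points lie on
the lattice.  The cubic lattice has 6 basis vectors of squared length 1,
the FCC lattice 12 of squared length 2; one neighbor step is scaled to
3.8 Å, the mean Cα–Cα distance.

The fit minimizes the superposition-free distance-matrix RMSD against the
native backbone `B = b_1 … b_n`:

    dRMSD(B, C) = sqrt( Σ_{i<j} ( d(b_i, b_j) − d(p_i, p_j) )² / (n(n−1)/2) )

Optimization is a constraint-based local search: a greedy chain-growth
initialization (place each residue at the free neighbor minimizing the
partial dRMSD, FIFO tie-breaks, backtracking on dead ends), then iterated
*pull* and *jump* moves with tabu memory.  Every candidate move is priced
without being committed; the best candidate **including the incumbent** is
accepted, so the objective never increases.  Stagnation triggers growth of
the jump-move size.

Energies are contact sums `E(C) = Σ_{i<j} contact(i,j) · energy(s_i, s_j)`
with `contact(i,j) = 1` when residues i, j occupy neighboring lattice
points (sequence-adjacent pairs excluded by default).  Three models ship:
`hp-basic` (−1 per hydrophobic–hydrophobic contact), `mj`
(Miyazawa–Jernigan 20×20 contact energies), and `bre` (a clearly-labelled
synthetic stand-in for an empirical contact potential; substitute your own
20×20 table by path).

## Worked example

Generate a synthetic 40-residue coil (3.8 Å bonds, excluded volume), fit it
to both lattices, then compare the dRMSD-guided sampler with a random walk:

```
$ pclfit synth --kind offlattice --n 40 --count 1 --seed 11 -o fixtures
$ pclfit fit fixtures/coil-n40-s11.pdb --lattice fcc   --seed 0 --iters 3000 -o fit_fcc
coil-n40-s11:A  n=40  fcc  initial 1.81 A  final 1.52 A
$ pclfit fit fixtures/coil-n40-s11.pdb --lattice cubic --seed 0 --iters 3000 -o fit_cubic
coil-n40-s11:A  n=40  cubic  initial 1.99 A  final 1.99 A
```

`initial` is the chain-growth dRMSD, `final` the best found by the search:
the FCC lattice, with twice the coordination number, fits the same chain
about 0.5 Å closer than the cubic lattice here.  `fit_fcc.pdb` holds the
fitted CA trace, `fit_fcc.json` the per-run numbers at full precision.

```
$ pclfit sample fixtures/coil-n40-s11.pdb --mode pclf       --samples 2000 --seed 0 -o coil__fcc__pclf.csv
coil-n40-s11:A  pclf  2000 records  min dRMSD 1.52 A -> coil__fcc__pclf.csv
$ pclfit sample fixtures/coil-n40-s11.pdb --mode randomwalk --samples 2000 --seed 0 -o coil__fcc__random-walk.csv
coil-n40-s11:A  random-walk  2000 records  min dRMSD 3.72 A -> coil__fcc__random-walk.csv
$ pclfit analyze coil__fcc__pclf.csv coil__fcc__random-walk.csv -o summary
    sampler   energy    >0  >0.5   <=0  <-0.5
       pclf hp-basic 100.0 100.0   0.0    0.0
       ...
protein_id lattice     pclf  random-walk
      coil     fcc 1.516656     3.715738
```

The trace CSVs record, per accepted candidate, its dRMSD and its energy
under all three models; `analyze` reports per-protein Spearman correlations
binned into >0 / >0.5 / ≤0 / <−0.5 (the first and third partition the
proteins) and the per-sampler minimum dRMSD — the guided search digs ~2.2 Å
deeper than the random walk on this chain.

The same machinery is available as a library:

```python
import pclfit as pf
B = pf.read_backbone("my_chain.pdb", chain_id="A")
result = pf.pclf_search(B, pf.FCC, pf.SearchConfig(seed=0, max_iterations=10_000))
print(result.initial_objective, result.best_objective)
```

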