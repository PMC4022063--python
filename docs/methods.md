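# Methods

## Lattices and scaling

Two lattices are supported.  The cubic lattice has 6 neighbor vectors of
squared length 1; the FCC lattice has 12 of squared length 2, stored in a
fixed canonical order that doubles as the FIFO tie-break order during chain
growth.  Two residues are in lattice contact exactly when their squared
distance equals the neighbor squared length (1 cubic, 2 FCC).  The Å scale
is fixed so one neighbor step spans 3.8 Å — the mean consecutive Cα–Cα
distance in proteins — i.e. 3.8 Å/unit on cubic and 3.8/√2 Å/unit on FCC.
Note the FCC neighbor "distance 2" is a *squared* distance; any other
reading would break the 3.8 Å bond length.

Conformation coordinates are confined to [−n, n] per axis for a chain of
length n (the chain starts at the origin and can never leave this box, and
move generation enforces it so drift cannot accumulate).

## Objective

The fit minimizes dRMSD, the RMS difference of all intramolecular pairwise
distances.  It needs no superposition and is invariant under rigid motions
and reflections of either structure, which also means the first lattice
step can be fixed during exhaustive enumeration without losing any optimum
(the lattice point groups act transitively on the basis vectors).
Internally all comparisons use the squared-error sum; the square root is
applied only for reporting.  A move counts as an improvement only if it
decreases the squared-error sum by more than 1e−12 absolute, which
prevents float-noise cycling.

Pricing a move is incremental: a distance cache stores the reference and
current distance matrices plus the running squared-error sum, and
simulating a relocation of k residues costs O(k·n) rather than O(n²).  The
running sum is refreshed from the matrix every 256 commits; over 10⁴-move
sequences the incremental and from-scratch values agree to ~1e−15
relative.  Inside the search, all candidates of one iteration are priced
in a single vectorized batch (from scratch for n ≤ 250, through the cache
above that); one currency is used per run so acceptance comparisons are
exact.

## Chain growth

The first residue is pinned at the origin.  Each next residue goes to the
free neighbor of the previous one minimizing the partial dRMSD of the
placed prefix; costs tied within 1e−12 resolve to the lowest basis index
(FIFO).  Dead ends trigger depth-first backtracking with per-position
tried-direction sets, bounded by a node-visit cap (default 10⁶) after
which growth continues greedily without backtracking — unbounded
backtracking is exponential in the worst case, and the cap is never
reached on realistic inputs.  The procedure is deterministic.  On
backbones that are exact scaled lattice walks a zero-cost direction exists
at every step, so chain growth alone recovers dRMSD 0.

## Local search

Each iteration picks pull or jump with probability ½ each, then a uniformly
random non-tabu position.

*Jump*: the residue is re-placed at any free point adjacent to both chain
neighbors (terminal residues: adjacent to their single neighbor).  When
the move size m exceeds 1, a contiguous run of m positions starting at the
chosen index is reoptimized by sequential per-index relocation, each
conditioned on the previous; the combination count is capped at 512 per
iteration.

*Pull*: the residue relocates to a free point L adjacent to one chain
neighbor (the anchor).  If the opposite bond survives, the move is a plain
relocation.  Otherwise either L is adjacent to the vacated position and
the tail follows the trail one step behind (possible on FCC, where the
difference of two basis vectors can itself be a basis vector), or a free
corner point adjacent to both L and the vacated position takes the next
residue and the tail follows two steps behind, stopping as soon as the
chain constraint is restored.  End residues may also drag the whole chain
reptation-style.  Both pull directions are generated; every candidate is
validated against all three constraints.

Acceptance is the argmin over all candidates plus the incumbent, so the
objective trace is monotone non-increasing, and a fixed seed reproduces a
run exactly.  Accepted positions become tabu for max(5, n/10) iterations
(the tabu list stores positions, not moves; retaining the incumbent does
not update it).  If the global best has not improved for `stagnation`
iterations (default 1000), the jump move size grows by one — capped at
min(5, n−2), beyond which the sequential-relocation neighborhood
degenerates — and the stagnation threshold is multiplied by `factor`
(default 1.5); both reset on the next improvement.  All of these are
`SearchConfig` fields.

## Energy models

Energies are contact sums over nonbonded pairs.  Sequence-adjacent pairs
are excluded by default: on FCC every bonded pair sits at contact
distance, contributing a sequence-dependent constant that no search
decision can change; `include_adjacent=True` restores the literal
all-pairs sum.  `hp-basic` scores −1 per H–H contact with hydrophobic
class {A, C, F, I, L, M, V, W, Y} (overridable); unknown residues count as
polar.  `mj` is the Miyazawa–Jernigan 1996 contact-energy table, vendored
as a plain-text 20×20 matrix.  `bre` is a **synthetic stand-in** for an
empirical contact potential — a hydrophobicity-product construction with
the right shape and sign structure, clearly labelled in its data file —
because the published matrix is not redistributable here; any 20×20 table
in the same text format can be loaded by path.  All tables are validated
symmetric on load.

## Samplers and correlation analysis

Five samplers emit one record per accepted candidate (iteration, dRMSD,
and the energy under all three models): the dRMSD-guided search itself;
three energy-guided variants (same search, objective swapped for the named
contact energy); and a random walk that starts from a randomized chain
growth (uniform choice among free directions) and accepts a uniformly
random valid neighbor each iteration.  Guided traces are monotone in their
own objective but not in dRMSD.

Per protein, the Spearman rank correlation (average ranks on ties, via
scipy) between an energy column and the dRMSD column measures whether
minimizing that energy tracks approach to the native structure; constant
columns yield an undefined coefficient, flagged NaN and excluded from
binning.  Coefficients are binned into >0, >0.5, ≤0, <−0.5, with ρ = 0
counted in ≤0 so the first and third bins partition the proteins.
Minimum-dRMSD tables pivot per-(protein, sampler) minima for scattering
each sampler against the random walk.

## Synthetic data

Three generators with fixed-seed determinism:

* **Exact walks** — uniform-step random self-avoiding walks (restarting on
  dead ends), scaled to Å and given a random rigid rotation plus a
  translation in [−20, 20] Å; by construction the generating walk achieves
  dRMSD 0, giving ground truth for recovery tests.
* **Perturbed walks** — the same plus iid Gaussian noise of scale σ per
  coordinate.  The generating walk then sits at dRMSD ≈ σ√2 (each pair
  distance perturbs with variance ≈ 2σ²), which bounds the achievable fit.
* **Off-lattice coils** — chains with exact 3.8 Å bonds, directions uniform
  on the sphere, rejection-sampled so nonbonded pairs stay ≥ 3.0 Å.  These
  reproduce the bond geometry and excluded volume of Cα traces but none of
  the secondary-structure or packing statistics of real proteins, so
  passing tests demonstrate correct optimization behavior on
  protein-*like* geometry, not predictive accuracy on real folds.

## Problem sizes and defaults

Experiments in the test suite and the reproduction script run at desk
scale, chosen as the package's own defaults: exact-recovery fixtures n =
10…50; oracle comparisons at n = 6 (cubic) / n = 5 (FCC) against exhaustive
enumeration (guarded to n ≤ 8 / n ≤ 6, branch-and-bound on the partial
squared-error sum); noise recovery at n = 30 with 2000 search iterations;
lattice comparison on n = 50 coils with 3000 iterations; sampler
comparisons with 10⁴ records.  For very long traces the samplers stream
CSV rather than hold records in memory-heavy structures.

## Known limitations

* The search is strictly monotone, as the acceptance rule dictates.  When
  greedy chain growth commits a large structural error — which starts to
  happen on perturbed walks around σ ≈ 0.3 Å at n = 30 — the search can
  land in local optima with no improving move at depth 1 or 2, and no
  amount of extra iterations, alternative seeds, or faster move-size
  escalation escapes them; measured recovery to within 3σ then drops to
  roughly 70% of instances, while σ ≤ 0.1 recovers essentially always.
  Randomized or restarted chain growth would mitigate this but is
  deliberately out of scope.
* The exact multi-point jump semantics and the pull-move variant of the
  original operator papers are not uniquely determined by their summary
  here; the sequential contiguous-run jump and the bidirectional
  trail-following pull above are this package's documented choices.
* The `bre` table is synthetic (see above); conclusions about that
  specific published potential require dropping in the real matrix.
* mmCIF, multi-model ensembles, side-chain atoms and cRMSD-with-
  superposition are not implemented; PDB reading keeps altloc ''/'A',
  ignores HETATM, and treats chain breaks as continuous with a warning.
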