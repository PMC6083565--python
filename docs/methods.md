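# Methods

## Model

Residues are classified hydrophobic (H) or polar (P); a conformation is a
self-avoiding walk on the 2D triangular lattice, encoded as absolute
direction labels d ∈ {1..6}, one per bond. The energy of a valid fold is
E = −h, where h counts pairs (i, j), j ≥ i+2, of H residues occupying
lattice-adjacent sites. Chain-consecutive pairs never count; (i, i+2) pairs
can, because the triangular lattice closes triangles. |ε| = 1, so energies
are integers. Axial coordinates (q, r) are used throughout, with the six
unit steps listed counterclockwise from (1, 0); two sites are adjacent iff
max(|Δq|, |Δr|, |Δq+Δr|) = 1. The label→vector assignment is a convention:
any assignment related to it by one of the 12 lattice point-group isometries
yields congruent folds with identical energies, so only literal direction
strings depend on it, never energies.

Binary benchmark notation maps 1 → H, 0 → P. The inverse convention exists
in the literature, but the packaged all-1 17-mer carries a negative printed
best energy, which is only possible if 1 is hydrophobic; the parser exposes
`one_is="P"` for sources using the opposite mapping.

## Invalid decodes

Roughly (1 − μ/6)ⁿ of random direction strings collide (μ ≈ 4.15 is the
lattice's connective constant), so the optimizer constantly meets invalid
decodes. Policy: a colliding decode has fitness equal to its number of
coincident residue pairs — strictly positive, so every valid fold (fitness
≤ 0) dominates every colliding one, and fewer collisions are always
preferred, giving the search a gradient toward validity. Contacts of
colliding decodes are ignored. A lexicographic variant (collisions first,
contacts as tie-break) was evaluated and bought nothing measurable, so the
simpler policy stands.

## Optimizer

Two populations of N = 100 real vectors in [1,6]^(n−1) (anions, cations) are
decoded by rounding half-away-from-zero with cyclic wrap
((round(x)−1) mod 6)+1 — directions are cyclic on the hexagon, so wrapping
avoids the boundary bias clamping would introduce. Updates keep real-valued
positions (the published update equations are real-valued; integer states
would make the attraction force meaningless) and decode only for scoring.

Liquid phase: A_{i,j} += AF·(Cbest_j − A_{i,j}) with
AF = 1/(1+exp(−0.1/AD)), AD = |A_{i,j} − Cbest_j| per coordinate (cations
symmetric toward Abest). AF ∈ (0.5, 1], so the population contracts onto
the opposite-charge best within a handful of iterations; all sustained
exploration therefore comes from the solid phase. Bests are all-time bests
per charge; strictly better fitness replaces the incumbent, ties keep it.
(A variant attracting toward the current iteration's bests was measured and
is clearly worse — elitist attractors win on every benchmark tried.)

Solid phase (default, stall-triggered): fires when both charges' bests have
failed to improve for more than `solid_num` consecutive iterations. Every
ion pair first receives the kick A_i += Φ₁·(Cbest − 1) or Φ₁·Cbest
(coin per pair, Φ ~ U[−1,1]; "−1" subtracts the scalar from every
coordinate); coordinates leaving [1,6] are snapped to their wrapped label.
Then each pair is re-initialised uniformly with probability 0.05, and is
otherwise refined by the greedy local search and written back as reals.
Re-initialised pairs supply restart diversity; refined pairs turn kicked
copies of the incumbent into basin-hopping steps. After firing, both stall
counters reset (otherwise the phase would fire every following iteration).
The greedy/re-initialise split deliberately mirrors the role the same
rand₃ < 0.05 draw plays in the classic solid phase, where it triggers
re-initialisation: assigning the local search to the rare branch instead
degenerates the phase into pure random restart, and measured best energies
drop by 4–6 contacts on the length-20–25 benchmarks. The classic solid
phase (guard CbestFit ≥ CworstFit/2 ∧ AbestFit ≥ AworstFit/2, taken
literally under minimisation, with re-initialisation at 0.05 and no local
search) ships as `solid_variant="original"` for fidelity; the guard is
ill-behaved once fitnesses go negative, which is why the stall-triggered
variant is the default.

Greedy local search: bonds visited in chain order, each selected
independently with probability `greedy_prob` (default 0.25); a selected
bond is replaced by the best of the six labels under full-chain fitness
(changing a label rigidly translates the whole tail; the chain is always
re-decoded and re-scored in full, collision policy included). Ties keep the
incumbent label; among non-incumbent ties the smallest label wins, making
the search deterministic given the selection draws. Sweeps repeat until one
yields no improvement (cap 20), i.e. the search terminates at a single-label
local optimum.

`solid_num` has no published value; the default is 50, and the short-chain
acceptance checks pass unchanged for 25, 50 and 100. All randomness flows
from one seeded generator; a full run is bit-reproducible, and batches use
consecutive seeds (seed, seed+1, …) for auditability. Stopping is the fixed
iteration budget (2000 by default); `target_energy` optionally stops a run
early once a known optimum is reached — off by default, used by benchmark
sweeps where only "did it reach the printed value" matters.

## Exhaustive oracle

Depth-first enumeration over direction strings with an occupied-site hash
map and incremental contact counting; no branch-and-bound (correctness
first — the pruning a bound adds is an optimisation, not a requirement at
these sizes). Symmetry fixing restricts the first step to label 1 and the
first turn to the upper half-plane, visiting one representative per
point-group orbit: every orbit has size 12 except the straight walk (fixed
by the axis reflection, orbit 6), so full counts satisfy
total = 12·fixed − 6 — an identity the tests assert. Fixing cannot change
the minimum energy. The default cap of 13 residues keeps the tree near 10⁶
nodes (the packaged 12-mer enumerates 1.47 M symmetry-fixed walks in
seconds); beyond the cap the oracle refuses and points to the optimizer.

## What the benchmarks show

The packaged instances are transcriptions of the two printed benchmark
tables (binary repeat notation, expanded and length-checked at test time;
two typesetting defects in the longest two rows are corrected to the
canonical literature sequences, as noted in the fixture source). The
printed "E" column is the best energy reported across prior methods, not a
certified optimum — the all-H 17-mer, printed −17, is reproducibly folded
to −20 by this implementation, and the 12-mer's printed −11 is confirmed
exact by enumeration.

Under the default budget (100 ions/charge × 2000 iterations, ≤ 30 seeded
runs with early stop) this implementation reaches the printed best energies
on the 12-mer (−11, = exact), the all-H 17-mer (−17, exceeded at −20) and
the 20-mer (−15). On the length-24 (−17) and length-25 (−12) instances it
plateaus 1–4 contacts short (typical best-of-batch −13 and −11); only tabu
search and hill-climbing/GA hybrids match those two printed values in the
comparison literature, and the single-label move neighbourhood used here
appears to be the binding constraint. The 37-mer (printed −29) is reported
as best-found-within-budget. Acceptance-script run counts are capped per
instance (3–12) so the full recomputation stays desk-scale; caps were
chosen by chain length, with the expensive long instances getting the
smallest counts.

## Limitations

- Single-label moves only: no pull/crankshaft/multi-bond moves, no tabu
  memory — by design, the local search is the published single-point one.
- The synthetic stand-ins for "hard" instances are the printed benchmarks
  themselves; no generator of random HP instances is included beyond
  uniform random conformations used in tests.
- 2D triangular lattice only; no square-lattice or 3D variants, no real
  (off-lattice) structures, and no reimplementation of the comparison
  algorithms whose results are cited in the benchmark tables.
- Energies assume |ε| = 1 and H–H contacts only; no mixed H–P potentials.
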