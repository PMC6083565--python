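# imogfold

Protein folding prediction in the hydrophobic–polar (HP) model on the 2D
triangular lattice, using an ions-motion optimizer hybridised with a greedy
local search (IMOG), together with an exhaustive enumeration oracle and the
standard printed benchmark instances.

## The problem

In the HP model a protein chain of *n* residues is reduced to a string
S = a₁…aₙ over {H, P}: hydrophobic or polar. A fold is a self-avoiding walk
P = p₁…pₙ on a lattice — here the triangular lattice, where every site has
six neighbours and the chain is encoded as a string of direction labels
d ∈ {1..6}, one per bond. The energy of a valid fold counts hydrophobic
contacts:

    E = −h,   h = #{ (i, j) : j ≥ i+2, aᵢ = aⱼ = H, pᵢ and pⱼ lattice-adjacent }

i.e. each pair of H residues that are neighbours on the lattice but not
consecutive along the chain contributes −1 (in units of |ε|). Unlike the
square lattice, (i, i+2) pairs can form contacts. Finding the minimum-energy
fold is NP-hard; the search space grows as 6ⁿ⁻¹.

The package is aimed at researchers studying lattice-protein optimisation
heuristics: it provides the optimizer, exact ground truth for short chains,
the 28 classic benchmark instances, and fold rendering.

## The algorithm

IMOG maintains two populations of N real-valued vectors in [1,6]ᴰ (D = n−1):
anions A and cations C, decoded to direction strings by rounding with cyclic
wrap. Each iteration:

1. score everyone (valid folds: E; colliding decodes: +collision count,
   so every valid fold dominates every invalid one);
2. update the global bests Abest, Cbest;
3. **liquid phase** — every anion moves toward the best cation (and vice
   versa) by the sigmoid attraction AF = 1/(1 + e^(−0.1/AD)), where
   AD = |A_{i,j} − Cbest_j| per coordinate: a strict contraction;
4. **solid phase** — once both bests have stalled for more than `solid_num`
   iterations, each ion pair receives a perturbation Φ·Cbest or Φ·(Cbest−1),
   Φ ~ U[−1,1], and is then either re-initialised uniformly (probability
   0.05) or refined by the greedy local search: bonds are visited in chain
   order, each selected with probability 0.25, and a selected bond is
   replaced by the best of the six direction labels under full-chain
   fitness, sweeping until no improvement remains.

Defaults are the published operating point: N = 100 per charge, 2000
iterations, greedy probability 0.25. For chains of ≤ 13 residues the
`oracle` module enumerates every self-avoiding walk (quotienting the 12-fold
lattice symmetry) and returns the exact optimum.

## Worked example

```python
from imogfold import IMOConfig, benchmark, run_imog
from imogfold.render import render_ascii

entry = benchmark(1, 1)            # 20 residues, best known energy -15
config = IMOConfig(seed=3, target_energy=entry.stated_best_energy)
result = run_imog(entry.sequence, config)
print(result.best_energy)
print(render_ascii(entry.sequence, result.best_embedding))
```

prints

```
-15
      P
     H H P
  P H H P
 P H H P
P H H H P
   P H P

H-H contacts (15): (1, 3), (1, 6), (1, 7), (3, 6), (6, 15), (7, 9), (7, 15),
(9, 12), (9, 14), (9, 15), (12, 14), (14, 18), (14, 20), (15, 18), (18, 20)
```

— the fold realises 15 hydrophobic contacts, matching the best energy
reported for this instance (the run stops as soon as the target is hit).
The `examples/` directory holds one short script per capability: parsing
and the benchmark tables, the exact oracle, a full optimizer run, batch
statistics, and rendering. A thin CLI wraps the same functions:

```sh
imogfold oracle --seq "1(10)_5_1"          # exact minimum of the 12-mer
imogfold run --seq HHPPHPHPHPHPHP --seed 1 # one optimizer run, JSON out
imogfold bench --table 2 --runs 5 --target # benchmark sweep, TSV out
```

Sequences may be given as H/P letters or as binary repeat notation
(`(010)_2` → `010010`, 1 = hydrophobic by default).

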