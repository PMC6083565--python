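"""Fold one benchmark sequence with the ions-motion + greedy optimizer.

Runs IMOG at the published operating point (100 ions per charge, 2000
iterations, greedy probability 0.25) on the 20-residue benchmark and draws
the best fold it finds.  The printed best-known energy for this instance
is -15; stopping at that target keeps the demo fast.
"""

from imogfold import IMOConfig, benchmark, run_imog
from imogfold.render import render_ascii

entry = benchmark(1, 1)
config = IMOConfig(seed=3, target_energy=entry.stated_best_energy)
result = run_imog(entry.sequence, config)

print(f"sequence {entry.sequence} (n={entry.sequence.n})")
print(f"best energy found: {result.best_energy} "
      f"(printed best known: {entry.stated_best_energy})")
print(f"direction string: {list(result.best_conformation)}")
print(f"iterations used: {result.iterations_used}")
print()
print(render_ascii(entry.sequence, result.best_embedding))
# Each '-1' of energy is one pair of hydrophobic residues adjacent on the
# lattice but not consecutive along the chain.
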