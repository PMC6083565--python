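"""Best/mean statistics over independent seeded runs.

Repeats the optimizer on one short benchmark with consecutive seeds and
summarises the per-run best energies, the stability view of a stochastic
search: 'best' shows what the method can reach, 'mean' how reliably it
gets there.  A reduced budget keeps the demo quick.
"""

from imogfold import IMOConfig, benchmark, run_batch
from imogfold.io import batch_to_tsv

entry = benchmark(2, 1)  # 12 residues, exact optimum -11
config = IMOConfig(n_ions=40, iterations=400, solid_num=25, seed=0, runs=10)
stats = run_batch(entry.sequence, config)

print(f"sequence {entry.sequence}")
print(f"per-run best energies: {stats.energies}")
print(f"best {stats.best}, mean {stats.mean:.2f} over {stats.runs} runs")
print()
print(batch_to_tsv([stats]))
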