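"""Parse HP sequences and inspect the packaged benchmark tables.

Prints the two benchmark tables (expanded from their printed repeat
notation) with lengths and best-known energies, and shows the repeat
notation expanding step.
"""

from imogfold import builtin_benchmarks, expand_notation, parse_hp_string

print("(010)_2 expands to:", expand_notation("(010)_2"))

seq = parse_hp_string("1(10)_5_1")  # binary with 1 = hydrophobic
print(f"binary '1(10)_5_1' -> {seq} ({seq.n} residues, "
      f"H at 1-based positions {seq.hydrophobic_indices})")

for table in (1, 2):
    print(f"\nBenchmark table {table}:")
    for e in builtin_benchmarks(table):
        stated = "  --" if e.stated_best_energy is None else f"{e.stated_best_energy:4d}"
        print(f"  {e.index:2d}  n={e.stated_length:2d}  E*={stated}  {e.raw_notation}")

# E* is the best energy reported in the literature for each instance (more
# negative = more H-H contacts = more stable fold); '--' where none is printed.
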