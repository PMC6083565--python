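"""Render a direction-encoded fold as ASCII art and SVG.

Decodes a direction string for the 14-residue example sequence, scores it,
and writes an SVG drawing (chain bonds solid, H-H contacts dotted) next to
this script.
"""

from pathlib import Path

from imogfold import HPSequence, decode, energy
from imogfold.render import render_ascii, render_svg

seq = HPSequence("HHPPHPHPHPHPHP", label="example-14")
# a compact fold found by the optimizer (10 H-H contacts)
directions = [1, 1, 3, 4, 3, 5, 3, 5, 5, 1, 5, 1, 5]

ev = energy(seq, directions)
points = decode(directions)
print(f"fold energy {ev.energy} with {ev.h} H-H contacts "
      f"(valid: {ev.valid})")
print(render_ascii(seq, points))

out = Path(__file__).with_name("fold.svg")
out.write_text(render_svg(seq, points))
print(f"wrote {out}")
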