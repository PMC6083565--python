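"""Fold rendering: ASCII sketches and SVG drawings with H-H contact edges.

Axial lattice coordinates (q, r) map to the plane as x = q + r/2,
y = r * sqrt(3)/2, which draws the triangular lattice with unit bond length.
SVG is emitted as plain XML: chain bonds solid, H-H contacts dotted red,
hydrophobic residues filled dark, polar residues hollow.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import contacts
from .sequences import HPSequence


def _to_xy(points: np.ndarray) -> np.ndarray:
    q = points[:, 0].astype(float)
    r = points[:, 1].astype(float)
    return np.stack([q + r / 2.0, r * math.sqrt(3.0) / 2.0], axis=1)


def render_ascii(seq: HPSequence, points: np.ndarray) -> str:
    """Character-grid sketch: residues at (2q + r, r), contacts listed below.

    The column skew keeps all six neighbour directions distinct on the grid;
    rows with larger r are printed higher (y grows upward).
    """
    cols = 2 * points[:, 0] + points[:, 1]
    rows = points[:, 1]
    cmin, rmin = cols.min(), rows.min()
    width = int(cols.max() - cmin) + 1
    height = int(rows.max() - rmin) + 1
    grid = [[" "] * width for _ in range(height)]
    for (c, r), res, i in zip(
        zip(cols - cmin, rows - rmin), seq.residues, range(1, seq.n + 1)
    ):
        cell = grid[height - 1 - int(r)][int(c)]
        grid[height - 1 - int(r)][int(c)] = res if cell == " " else "*"
    lines = ["".join(row).rstrip() for row in grid]
    pairs = contacts(seq, points)
    lines.append("")
    lines.append(f"H-H contacts ({len(pairs)}): " + ", ".join(map(str, pairs)))
    return "\n".join(lines) + "\n"


def render_svg(seq: HPSequence, points: np.ndarray, scale: float = 40.0) -> str:
    """Standalone SVG drawing of the fold with dotted H-H contact edges."""
    xy = _to_xy(points) * scale
    pad = scale * 0.8
    xy[:, 0] -= xy[:, 0].min() - pad
    xy[:, 1] = xy[:, 1].max() - xy[:, 1] + pad  # flip: SVG y grows downward
    width = xy[:, 0].max() + pad
    height = xy[:, 1].max() + pad

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        f'<rect width="{width:.0f}" height="{height:.0f}" fill="white"/>',
    ]
    for (i, j) in contacts(seq, points):
        (x1, y1), (x2, y2) = xy[i - 1], xy[j - 1]
        parts.append(
            f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
            f'stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>'
        )
    for k in range(seq.n - 1):
        (x1, y1), (x2, y2) = xy[k], xy[k + 1]
        parts.append(
            f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
            f'stroke="black" stroke-width="2"/>'
        )
    for k, res in enumerate(seq.residues):
        x, y = xy[k]
        fill = "#333333" if res == "H" else "white"
        parts.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{scale * 0.22:.1f}" '
            f'fill="{fill}" stroke="black" stroke-width="1.5"/>'
        )
        parts.append(
            f'<text x="{x:.1f}" y="{y - scale * 0.3:.1f}" font-size="{scale * 0.25:.0f}" '
            f'text-anchor="middle" fill="#666666">{k + 1}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
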