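"""Triangular-lattice geometry: direction codes, decoding, adjacency, self-avoidance.

Conformations are strings of direction labels in {1..6}, one per chain bond.
Lattice sites use integer axial coordinates (q, r); the six unit steps are the
neighbours of the origin, listed counterclockwise starting from (1, 0).  With
this vector set two sites are adjacent exactly when their difference (dq, dr)
satisfies max(|dq|, |dr|, |dq + dr|) == 1, so every geometric test is integer
arithmetic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

#: Canonical direction map: label -> axial unit step, counterclockwise from (1, 0).
DIRECTION_VECTORS: dict[int, tuple[int, int]] = {
    1: (1, 0),
    2: (0, 1),
    3: (-1, 1),
    4: (-1, 0),
    5: (0, -1),
    6: (1, -1),
}

#: Same map as a (7, 2) lookup array (row 0 unused) for vectorised decoding.
_STEP_TABLE = np.zeros((7, 2), dtype=np.int64)
for _label, _vec in DIRECTION_VECTORS.items():
    _STEP_TABLE[_label] = _vec

LatticePoint = tuple[int, int]


def neighbors(p: LatticePoint) -> set[LatticePoint]:
    """The six lattice sites adjacent to ``p``."""
    q, r = p
    return {(q + dq, r + dr) for dq, dr in DIRECTION_VECTORS.values()}


def are_adjacent(p: LatticePoint, q: LatticePoint) -> bool:
    dq = p[0] - q[0]
    dr = p[1] - q[1]
    return max(abs(dq), abs(dr), abs(dq + dr)) == 1


def validate_conformation(directions: Sequence[int]) -> np.ndarray:
    """Return ``directions`` as an int array, rejecting labels outside {1..6}."""
    conf = np.asarray(directions, dtype=np.int64)
    if conf.ndim != 1:
        raise ValueError("a conformation must be a flat sequence of direction labels")
    if conf.size and (conf.min() < 1 or conf.max() > 6):
        bad = conf[(conf < 1) | (conf > 6)][0]
        raise ValueError(f"direction label {bad} outside the valid range 1..6")
    return conf


def decode(directions: Sequence[int]) -> np.ndarray:
    """Decode a direction string into lattice coordinates.

    Returns an (n, 2) integer array of axial coordinates with the first residue
    at the origin; ``n = len(directions) + 1``.  Collisions are *not* checked
    here — validity is a separate question (:func:`is_self_avoiding`).
    """
    conf = validate_conformation(directions)
    points = np.zeros((conf.size + 1, 2), dtype=np.int64)
    if conf.size:
        np.cumsum(_STEP_TABLE[conf], axis=0, out=points[1:])
    return points


def collision_count(points: np.ndarray) -> int:
    """Number of unordered pairs of residues occupying the same site."""
    _, counts = np.unique(points, axis=0, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def is_self_avoiding(points: np.ndarray) -> tuple[bool, int]:
    """Whether all residues occupy distinct sites, plus the collision count."""
    ncoll = collision_count(points)
    return ncoll == 0, ncoll


# ---------------------------------------------------------------------------
# Point-group isometries (used by symmetry tests and the enumeration oracle).
# ---------------------------------------------------------------------------

def rotate60(points: np.ndarray) -> np.ndarray:
    """Rotate axial coordinates by 60 degrees counterclockwise about the origin."""
    q, r = points[..., 0], points[..., 1]
    return np.stack([-r, q + r], axis=-1)


def reflect_axis(points: np.ndarray) -> np.ndarray:
    """Reflect across the axis through the origin and direction 1."""
    q, r = points[..., 0], points[..., 1]
    return np.stack([q + r, -r], axis=-1)


def point_group() -> list:
    """The 12 isometries of the triangular lattice fixing the origin.

    Returned as callables on (…, 2) coordinate arrays: six rotations, each
    optionally composed with the axis reflection.
    """
    ops = []
    for k in range(6):
        for reflect in (False, True):
            def op(points, k=k, reflect=reflect):
                out = np.asarray(points)
                if reflect:
                    out = reflect_axis(out)
                for _ in range(k):
                    out = rotate60(out)
                return out
            ops.append(op)
    return ops
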