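"""HP contact energy on the triangular lattice.

The energy of a self-avoiding fold is ``E = -h`` where ``h`` counts H-H
contacts: pairs of hydrophobic residues that are lattice-adjacent but at least
two apart along the chain (``j >= i + 2``).  On the triangular lattice the
pair (i, i+2) *can* be a contact, unlike on the square lattice.  Colliding
(non-self-avoiding) decodes get a strictly positive surrogate fitness equal to
their collision count, so every valid fold dominates every invalid one and the
optimizer is pulled toward fewer collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import collision_count, decode
from .sequences import HPSequence


@dataclass(frozen=True)
class EnergyValue:
    """Energy of one conformation: ``E = -h`` when valid, else ``+collisions``."""

    energy: int          # -h for valid conformations; 0 placeholder when invalid
    h: int               # number of H-H contacts (0 when invalid)
    valid: bool
    collision_count: int

    @property
    def fitness(self) -> int:
        """Minimisation objective: E when valid, +collision_count otherwise."""
        return self.energy if self.valid else self.collision_count


def contacts(seq: HPSequence, points: np.ndarray) -> list[tuple[int, int]]:
    """H-H contact pairs of an embedding, as sorted 1-based index pairs.

    ``points`` must hold one lattice site per residue and be self-avoiding.
    """
    if len(points) != seq.n:
        raise ValueError(
            f"embedding has {len(points)} points for a {seq.n}-residue sequence"
        )
    h_idx = np.flatnonzero(seq.hp_mask())
    out: list[tuple[int, int]] = []
    for a in range(len(h_idx)):
        for b in range(a + 1, len(h_idx)):
            i, j = int(h_idx[a]), int(h_idx[b])
            if j - i < 2:
                continue
            dq = int(points[i, 0] - points[j, 0])
            dr = int(points[i, 1] - points[j, 1])
            if max(abs(dq), abs(dr), abs(dq + dr)) == 1:
                out.append((i + 1, j + 1))
    return out


def energy(seq: HPSequence, conf: Sequence[int]) -> EnergyValue:
    """Decode a direction string and score it under the contact potential."""
    conf = np.asarray(conf)
    if conf.size != seq.n - 1:
        raise ValueError(
            f"conformation has {conf.size} directions for a {seq.n}-residue sequence"
        )
    points = decode(conf)
    ncoll = collision_count(points)
    if ncoll:
        return EnergyValue(energy=0, h=0, valid=False, collision_count=ncoll)
    h = len(contacts(seq, points))
    return EnergyValue(energy=-h, h=h, valid=True, collision_count=0)


def fitness(seq: HPSequence, conf: Sequence[int]) -> int:
    return energy(seq, conf).fitness


# ---------------------------------------------------------------------------
# Vectorised batch scoring (the optimizer's inner loop)
# ---------------------------------------------------------------------------

from .lattice import _STEP_TABLE  # noqa: E402  (shared direction lookup)


def batch_decode(confs: np.ndarray) -> np.ndarray:
    """Decode a (m, n-1) matrix of direction labels to (m, n, 2) coordinates."""
    m, d = confs.shape
    points = np.zeros((m, d + 1, 2), dtype=np.int64)
    np.cumsum(_STEP_TABLE[confs], axis=1, out=points[:, 1:])
    return points


def batch_fitness(hp_mask: np.ndarray, confs: np.ndarray) -> np.ndarray:
    """Fitness of many conformations at once.

    ``hp_mask`` is the boolean H indicator of the sequence (length n); ``confs``
    is (m, n-1) with labels in {1..6}.  Returns an (m,) integer array: -h for
    self-avoiding rows, +collision count otherwise.  All-pairs arithmetic on
    axial coordinates; O(m n^2) but a handful of numpy passes.
    """
    points = batch_decode(confs)
    n = points.shape[1]
    dq = points[:, :, None, 0] - points[:, None, :, 0]
    dr = points[:, :, None, 1] - points[:, None, :, 1]
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)

    coincident = (dq == 0) & (dr == 0) & upper
    ncoll = coincident.sum(axis=(1, 2))

    adjacent = (
        (np.abs(dq) <= 1) & (np.abs(dr) <= 1) & (np.abs(dq + dr) <= 1)
        & ~((dq == 0) & (dr == 0))
    )
    hh = hp_mask[:, None] & hp_mask[None, :]
    chain_gap = np.triu(np.ones((n, n), dtype=bool), k=2)
    h_counts = (adjacent & hh & chain_gap).sum(axis=(1, 2))

    return np.where(ncoll > 0, ncoll, -h_counts)
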