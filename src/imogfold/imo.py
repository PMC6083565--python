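"""Ions-motion optimizer core: population state, liquid phase, solid phases.

Two oppositely charged sub-populations of real-valued vectors search the space
of direction strings.  In the liquid phase each anion is attracted toward the
best cation (and vice versa) by a sigmoid force of their per-coordinate
distance, a strict contraction.  When both global bests stagnate, a solid
phase perturbs, re-initialises, or (in the improved variant) greedily refines
individuals to escape the local optimum.

Positions live in the continuous box [1, 6]^D and are decoded to integer
direction labels only for scoring: the published update equations are
real-valued even though the genotype is discrete.  Labels are cyclic on the
hexagon, so out-of-range coordinates wrap modularly rather than clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np

from .greedy import greedy_local_search
from .sequences import HPSequence

#: Scale of the sigmoid attraction force (from the force law 1/(1+e^{-0.1/d})).
FORCE_SCALE = 0.1

FitnessFn = Callable[[np.ndarray], np.ndarray]  # (m, D) int labels -> (m,) fitness


@dataclass(frozen=True)
class IMOConfig:
    """Tunables of the optimizer.

    Defaults are the published operating point: 100 anions + 100 cations,
    2000 iterations, greedy mutation probability 0.25 per bond, and the
    improved (stall-triggered) solid phase.
    """

    n_ions: int = 100          # population size per charge
    iterations: int = 2000
    greedy_prob: float = 0.25  # per-bond selection probability in the greedy sweep
    solid_num: int = 50        # stall length (iterations) that triggers the solid phase
    reinit_prob: float = 0.05  # rand3 threshold inside the solid phase
    solid_variant: str = "improved"  # "improved" (default) or "original"
    seed: int = 0
    runs: int = 30
    target_energy: int | None = None  # optional early stop, off by default

    def validate(self) -> "IMOConfig":
        problems = []
        if self.n_ions < 1:
            problems.append(f"n_ions must be >= 1 (got {self.n_ions})")
        if self.iterations < 1:
            problems.append(f"iterations must be >= 1 (got {self.iterations})")
        if self.solid_num < 1:
            problems.append(f"solid_num must be >= 1 (got {self.solid_num})")
        if self.runs < 1:
            problems.append(f"runs must be >= 1 (got {self.runs})")
        if not 0.0 <= self.greedy_prob <= 1.0:
            problems.append(f"greedy_prob must be in [0, 1] (got {self.greedy_prob})")
        if not 0.0 <= self.reinit_prob <= 1.0:
            problems.append(f"reinit_prob must be in [0, 1] (got {self.reinit_prob})")
        if self.solid_variant not in ("improved", "original"):
            problems.append(
                f"solid_variant must be 'improved' or 'original' (got {self.solid_variant!r})"
            )
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))
        return self

    def replace(self, **kwargs) -> "IMOConfig":
        return replace(self, **kwargs).validate()

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "IMOConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class Population:
    """Anion and cation position matrices plus their current fitnesses."""

    anions: np.ndarray    # (N, D) float in [1, 6]
    cations: np.ndarray   # (N, D) float in [1, 6]
    anion_fit: np.ndarray
    cation_fit: np.ndarray

    @property
    def n(self) -> int:
        return self.anions.shape[0]

    @property
    def dim(self) -> int:
        return self.anions.shape[1]


@dataclass
class BestRecord:
    """Global bests, current worsts, and stall counters for both charges."""

    abest: np.ndarray = field(default_factory=lambda: np.empty(0))
    cbest: np.ndarray = field(default_factory=lambda: np.empty(0))
    abest_fit: float = np.inf
    cbest_fit: float = np.inf
    aworst_fit: float = -np.inf
    cworst_fit: float = -np.inf
    abest_stall: int = 0
    cbest_stall: int = 0

    def update(self, pop: Population) -> None:
        """Refresh bests/worsts from current fitnesses; maintain stall counters.

        Strictly better fitness replaces the incumbent best and resets the
        corresponding stall counter; ties keep the incumbent and count as a
        stalled iteration.
        """
        ai = int(np.argmin(pop.anion_fit))
        if pop.anion_fit[ai] < self.abest_fit:
            self.abest_fit = float(pop.anion_fit[ai])
            self.abest = pop.anions[ai].copy()
            self.abest_stall = 0
        else:
            self.abest_stall += 1
        ci = int(np.argmin(pop.cation_fit))
        if pop.cation_fit[ci] < self.cbest_fit:
            self.cbest_fit = float(pop.cation_fit[ci])
            self.cbest = pop.cations[ci].copy()
            self.cbest_stall = 0
        else:
            self.cbest_stall += 1
        self.aworst_fit = float(pop.anion_fit.max())
        self.cworst_fit = float(pop.cation_fit.max())


# ---------------------------------------------------------------------------
# Genotype decoding
# ---------------------------------------------------------------------------

def discretize(positions: np.ndarray) -> np.ndarray:
    """Real coordinates -> direction labels in {1..6}.

    Round half away from zero, then wrap cyclically: ((round(x) - 1) mod 6) + 1.
    """
    x = np.asarray(positions)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return ((rounded.astype(np.int64) - 1) % 6) + 1


def wrap_positions(positions: np.ndarray) -> np.ndarray:
    """Snap coordinates that left [1, 6] back via the cyclic wrap; keep the rest."""
    out = np.asarray(positions, dtype=float).copy()
    oob = (out < 1.0) | (out > 6.0)
    if oob.any():
        out[oob] = discretize(out[oob]).astype(float)
    return out


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------

def init_population(
    n_residues: int, config: IMOConfig, rng: np.random.Generator, evaluate: FitnessFn
) -> Population:
    """Uniform random positions in [1, 6]^D for both charges, scored."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    d = n_residues - 1
    anions = rng.uniform(1.0, 6.0, size=(config.n_ions, d))
    cations = rng.uniform(1.0, 6.0, size=(config.n_ions, d))
    return Population(
        anions=anions,
        cations=cations,
        anion_fit=evaluate(discretize(anions)),
        cation_fit=evaluate(discretize(cations)),
    )


def attraction_force(distance: np.ndarray | float) -> np.ndarray | float:
    """Sigmoid attraction 1/(1 + exp(-0.1/d)); 1 at d=0, 0.5 in the far limit."""
    d = np.asarray(distance, dtype=float)
    out = np.ones_like(d)
    nz = d > 0
    with np.errstate(over="ignore"):
        out[nz] = 1.0 / (1.0 + np.exp(-FORCE_SCALE / d[nz]))
    if out.ndim == 0:
        return float(out)
    return out


def liquid_phase_update(pop: Population, best: BestRecord) -> None:
    """Attract each anion toward the best cation and vice versa (in place).

    Per coordinate: A += AF * (Cbest - A) with AF the sigmoid force of the
    distance |A - Cbest|; since AF in (0, 1], positions stay inside [1, 6].
    """
    af = attraction_force(np.abs(pop.anions - best.cbest[None, :]))
    pop.anions += af * (best.cbest[None, :] - pop.anions)
    cf = attraction_force(np.abs(pop.cations - best.abest[None, :]))
    pop.cations += cf * (best.abest[None, :] - pop.cations)


def _phi_perturbation(
    pop: Population, best: BestRecord, rng: np.random.Generator
) -> None:
    """The shared solid-phase kick: A_i += Phi1 * (Cbest - 1) or Phi1 * Cbest.

    Phi ~ U[-1, 1] and the branch coin are drawn per individual; "Cbest - 1"
    subtracts the scalar 1 from every coordinate.
    """
    n = pop.n
    phi1 = rng.uniform(-1.0, 1.0, size=n)
    rand1 = rng.random(n)
    target_a = np.where(rand1[:, None] > 0.5, best.cbest[None, :] - 1.0, best.cbest[None, :])
    pop.anions += phi1[:, None] * target_a
    phi2 = rng.uniform(-1.0, 1.0, size=n)
    rand2 = rng.random(n)
    target_c = np.where(rand2[:, None] > 0.5, best.abest[None, :] - 1.0, best.abest[None, :])
    pop.cations += phi2[:, None] * target_c


def solid_phase_original(
    pop: Population,
    best: BestRecord,
    config: IMOConfig,
    rng: np.random.Generator,
    evaluate: FitnessFn,
) -> bool:
    """Original solid phase, guarded by the halved-worst condition.

    Fires when CbestFit >= CworstFit/2 and AbestFit >= AworstFit/2 (taken
    literally under minimisation).  Each ion pair gets the Phi kick and, with
    probability ``reinit_prob``, a fresh uniform position.  Returns whether it
    fired.  Kept for fidelity; the improved variant is the default.
    """
    if not (
        best.cbest_fit >= best.cworst_fit / 2.0
        and best.abest_fit >= best.aworst_fit / 2.0
    ):
        return False
    _phi_perturbation(pop, best, rng)
    reinit = rng.random(pop.n) < config.reinit_prob
    if reinit.any():
        k = int(reinit.sum())
        pop.anions[reinit] = rng.uniform(1.0, 6.0, size=(k, pop.dim))
        pop.cations[reinit] = rng.uniform(1.0, 6.0, size=(k, pop.dim))
    pop.anions = wrap_positions(pop.anions)
    pop.cations = wrap_positions(pop.cations)
    pop.anion_fit = evaluate(discretize(pop.anions))
    pop.cation_fit = evaluate(discretize(pop.cations))
    return True


def solid_phase_improved(
    pop: Population,
    best: BestRecord,
    config: IMOConfig,
    rng: np.random.Generator,
    evaluate: FitnessFn,
    seq: HPSequence,
) -> bool:
    """Improved solid phase: stall-triggered, with embedded greedy local search.

    Fires only when BOTH global bests have stalled for more than ``solid_num``
    iterations.  After the Phi kick, each ion pair is re-initialised uniformly
    with probability ``reinit_prob`` (the role the rand3 < 0.05 draw plays in
    the original solid phase) and otherwise refined by the greedy local search
    run to a single-label local optimum.  Re-initialised pairs supply restart
    diversity; refined pairs turn the kicked copies of the incumbent best into
    basin-hopping steps.  Returns whether it fired.
    """
    if not (best.abest_stall > config.solid_num and best.cbest_stall > config.solid_num):
        return False
    _phi_perturbation(pop, best, rng)
    pop.anions = wrap_positions(pop.anions)
    pop.cations = wrap_positions(pop.cations)
    rand3 = rng.random(pop.n)
    reinit_rows = np.flatnonzero(rand3 < config.reinit_prob)
    greedy_rows = np.flatnonzero(rand3 >= config.reinit_prob)
    if reinit_rows.size:
        k = reinit_rows.size
        pop.anions[reinit_rows] = rng.uniform(1.0, 6.0, size=(k, pop.dim))
        pop.cations[reinit_rows] = rng.uniform(1.0, 6.0, size=(k, pop.dim))
    for i in greedy_rows:
        conf, _ = greedy_local_search(
            seq, discretize(pop.anions[i]), config.greedy_prob, rng
        )
        pop.anions[i] = conf.astype(float)
        conf, _ = greedy_local_search(
            seq, discretize(pop.cations[i]), config.greedy_prob, rng
        )
        pop.cations[i] = conf.astype(float)
    pop.anion_fit = evaluate(discretize(pop.anions))
    pop.cation_fit = evaluate(discretize(pop.cations))
    return True
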