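"""IMOG orchestration: single runs, stall bookkeeping, and multi-run batches.

One run follows the six-step loop: initialise both charged populations,
score them, refresh the global bests, apply the liquid-phase attraction,
conditionally apply the solid phase, and repeat for a fixed iteration budget.
The best *valid* (self-avoiding) conformation ever decoded is the result.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np

from .energy import batch_fitness
from .imo import (
    BestRecord,
    IMOConfig,
    Population,
    discretize,
    init_population,
    liquid_phase_update,
    solid_phase_improved,
    solid_phase_original,
)
from .lattice import decode
from .sequences import HPSequence

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    sequence: HPSequence
    seed: int
    success: bool
    best_energy: int | None
    best_conformation: np.ndarray | None
    best_embedding: np.ndarray | None
    history: np.ndarray            # best-so-far fitness per iteration, non-increasing
    iterations_used: int

    def to_dict(self) -> dict:
        return {
            "label": self.sequence.label,
            "sequence": str(self.sequence),
            "seed": self.seed,
            "success": self.success,
            "best_energy": self.best_energy,
            "directions": (
                None
                if self.best_conformation is None
                else [int(d) for d in self.best_conformation]
            ),
            "coordinates": (
                None
                if self.best_embedding is None
                else [[int(q), int(r)] for q, r in self.best_embedding]
            ),
            "iterations_used": self.iterations_used,
        }


@dataclass
class BatchStats:
    """Best/mean summary over independent runs, one seed per run."""

    sequence: HPSequence
    config: IMOConfig
    per_run: list[RunResult]

    @property
    def runs(self) -> int:
        return len(self.per_run)

    @property
    def energies(self) -> list[int]:
        return [r.best_energy for r in self.per_run if r.success]

    @property
    def best(self) -> int | None:
        e = self.energies
        return min(e) if e else None

    @property
    def mean(self) -> float | None:
        e = self.energies
        return float(np.mean(e)) if e else None


class _Tracker:
    """Keeps the best valid conformation seen across all evaluations."""

    def __init__(self) -> None:
        self.best_fit = np.inf
        self.best_conf: np.ndarray | None = None

    def observe(self, pop: Population) -> None:
        for positions, fits in (
            (pop.anions, pop.anion_fit),
            (pop.cations, pop.cation_fit),
        ):
            i = int(np.argmin(fits))
            if fits[i] < self.best_fit and fits[i] <= 0:  # valid folds score <= 0
                self.best_fit = float(fits[i])
                self.best_conf = discretize(positions[i])


def run_imog(seq: HPSequence, config: IMOConfig | None = None) -> RunResult:
    """One seeded IMOG run on ``seq``; returns the best valid fold found."""
    config = (config or IMOConfig()).validate()
    if seq.n < 2:
        raise ValueError("sequence must have at least 2 residues")
    rng = np.random.default_rng(config.seed)
    evaluate = functools.partial(batch_fitness, seq.hp_mask())

    pop = init_population(seq.n, config, rng, evaluate)
    best = BestRecord()
    tracker = _Tracker()
    tracker.observe(pop)

    history = np.empty(config.iterations, dtype=float)
    iterations_used = 0
    for it in range(config.iterations):
        best.update(pop)
        history[it] = min(tracker.best_fit, best.abest_fit, best.cbest_fit)
        iterations_used = it + 1
        log.debug("iteration %d: best fitness %s", it + 1, history[it])
        if (
            config.target_energy is not None
            and tracker.best_fit <= config.target_energy
        ):
            break

        liquid_phase_update(pop, best)
        pop.anion_fit = evaluate(discretize(pop.anions))
        pop.cation_fit = evaluate(discretize(pop.cations))
        tracker.observe(pop)

        if config.solid_variant == "improved":
            fired = solid_phase_improved(pop, best, config, rng, evaluate, seq)
        else:
            fired = solid_phase_original(pop, best, config, rng, evaluate)
        if fired:
            best.abest_stall = 0
            best.cbest_stall = 0
            tracker.observe(pop)

    if tracker.best_conf is None:
        return RunResult(
            sequence=seq,
            seed=config.seed,
            success=False,
            best_energy=None,
            best_conformation=None,
            best_embedding=None,
            history=history[:iterations_used],
            iterations_used=iterations_used,
        )
    conf = tracker.best_conf
    return RunResult(
        sequence=seq,
        seed=config.seed,
        success=True,
        best_energy=int(tracker.best_fit),
        best_conformation=conf,
        best_embedding=decode(conf),
        history=history[:iterations_used],
        iterations_used=iterations_used,
    )


def run_batch(seq: HPSequence, config: IMOConfig | None = None) -> BatchStats:
    """``config.runs`` independent runs with seeds seed, seed+1, ...

    With a ``target_energy`` set the batch stops early once some run attains
    it (the remaining seeds are skipped), which keeps benchmark sweeps cheap
    when only the best energy matters.
    """
    config = (config or IMOConfig()).validate()
    results: list[RunResult] = []
    for i in range(config.runs):
        res = run_imog(seq, config.replace(seed=config.seed + i))
        results.append(res)
        if (
            config.target_energy is not None
            and res.success
            and res.best_energy is not None
            and res.best_energy <= config.target_energy
        ):
            break
    return BatchStats(sequence=seq, config=config, per_run=results)
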