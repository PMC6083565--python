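"""Greedy local search: re-optimise single direction labels under full-chain fitness.

Changing the label of bond ``k`` rigidly moves the whole chain tail, so every
candidate is re-decoded and re-scored in full, collisions included.  The search
is deliberately myopic — one label at a time, best of the six — which is what
makes it cheap enough to embed inside the optimizer's stagnation phase.
"""

from __future__ import annotations

import numpy as np

from .energy import batch_fitness
from .sequences import HPSequence

_LABELS = np.arange(1, 7)


def greedy_point_search(
    seq: HPSequence, conf: np.ndarray, index: int
) -> tuple[np.ndarray, int]:
    """Best single-label replacement at 1-based bond ``index``.

    Evaluates the six candidate labels under the full-chain fitness and returns
    ``(conformation, fitness)``.  The incumbent label is kept on ties; among
    non-incumbent ties the smallest label wins.
    """
    conf = np.asarray(conf, dtype=np.int64)
    if not 1 <= index <= seq.n - 1:
        raise IndexError(f"bond index {index} outside 1..{seq.n - 1}")
    candidates = np.repeat(conf[None, :], 6, axis=0)
    candidates[:, index - 1] = _LABELS
    fits = batch_fitness(seq.hp_mask(), candidates)
    incumbent = int(conf[index - 1])
    best_fit = int(fits.min())
    if int(fits[incumbent - 1]) == best_fit:
        return conf, best_fit  # incumbent-preserving tie-break
    label = int(_LABELS[np.flatnonzero(fits == best_fit)[0]])
    out = conf.copy()
    out[index - 1] = label
    return out, best_fit


def greedy_sweep(
    seq: HPSequence,
    conf: np.ndarray,
    prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Bernoulli sweep of :func:`greedy_point_search` over bonds in chain order.

    Each bond is selected independently with probability ``prob``; selected
    bonds are improved sequentially, so later searches see earlier
    improvements.  Returns the final conformation and its fitness.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    conf = np.asarray(conf, dtype=np.int64)
    selected = np.flatnonzero(rng.random(conf.size) < prob)
    fit = int(batch_fitness(seq.hp_mask(), conf[None, :])[0])
    for pos in selected:
        conf, fit = greedy_point_search(seq, conf, int(pos) + 1)
    return conf, fit


def greedy_local_search(
    seq: HPSequence,
    conf: np.ndarray,
    prob: float,
    rng: np.random.Generator,
    max_sweeps: int = 20,
) -> tuple[np.ndarray, int]:
    """Run :func:`greedy_sweep` repeatedly until a sweep yields no improvement.

    This is the local search proper: it terminates at (an approximation of) a
    single-label local optimum.  ``max_sweeps`` bounds the work on long chains;
    in practice a handful of sweeps suffices.
    """
    conf = np.asarray(conf, dtype=np.int64)
    prev: int | None = None
    fit = int(batch_fitness(seq.hp_mask(), conf[None, :])[0])
    for _ in range(max_sweeps):
        conf, fit = greedy_sweep(seq, conf, prob, rng)
        if prev is not None and fit >= prev:
            break
        prev = fit
    return conf, fit
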