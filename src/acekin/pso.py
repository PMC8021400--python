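"""Seeded global particle-swarm optimiser.

Standard global-best PSO with constriction-style coefficients
(w = 0.729, c1 = c2 = 1.49445), uniform initialisation inside the box,
velocity clamping to the box span and reflecting boundaries.  Determinism:
all randomness flows from one integer seed.  An optional patience-based
early stop halts the search when the best value has not improved by a
relative ``ftol`` for ``patience`` consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["PSOResult", "particle_swarm_minimize"]


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    trace: list[float] = field(default_factory=list)
    stopped_early: bool = False


def particle_swarm_minimize(
    func: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    seed: int,
    n_particles: int = 50,
    n_iter: int = 2000,
    w: float = 0.729,
    c1: float = 1.49445,
    c2: float = 1.49445,
    ftol: float = 1e-4,
    patience: int | None = 30,
    x0: np.ndarray | None = None,
) -> PSOResult:
    """Minimise ``func`` over a box. ``x0`` (optional) seeds one particle."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    span = hi - lo
    ndim = len(bounds)

    pos = lo + rng.random((n_particles, ndim)) * span
    if x0 is not None:
        pos[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    vel = (rng.random((n_particles, ndim)) - 0.5) * span
    vmax = 0.5 * span

    pbest = pos.copy()
    pbest_val = np.array([func(x) for x in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    n_eval = n_particles
    trace = [gbest_val]
    stale = 0
    stopped_early = False

    it = 0
    for it in range(1, n_iter + 1):
        r1 = rng.random((n_particles, ndim))
        r2 = rng.random((n_particles, ndim))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        # reflect at the box edges
        over_lo = pos < lo
        over_hi = pos > hi
        pos = np.where(over_lo, 2 * lo - pos, pos)
        pos = np.where(over_hi, 2 * hi - pos, pos)
        np.clip(pos, lo, hi, out=pos)
        vel = np.where(over_lo | over_hi, -vel, vel)

        vals = np.array([func(x) for x in pos])
        n_eval += n_particles
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        prev_best = gbest_val
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace.append(gbest_val)

        if patience is not None:
            rel = (prev_best - gbest_val) / max(abs(prev_best), 1e-300)
            stale = stale + 1 if rel < ftol else 0
            if stale >= patience:
                stopped_early = True
                break

    return PSOResult(
        x=gbest, fun=gbest_val, n_iter=it, n_eval=n_eval, trace=trace,
        stopped_early=stopped_early,
    )
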