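"""Dynamic multi-swarm particle swarm optimisation (DMS-PSO).

Particles follow the local-best velocity update
``v ← ω v + c1 r1 (pbest − x) + c2 r2 (lbest_j − x)``, with velocities
capped at ±v_max, positions clamped to the search box, and the whole swarm
randomly reshuffled into equal-size sub-swarms every ``regroup_period``
iterations so good solutions propagate between sub-swarms. Minimisation
convention throughout; non-finite fitness values are treated as +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["PsoConfig", "SwarmState", "OptimizeResult", "init_swarm", "step", "regroup", "optimize"]


@dataclass(frozen=True)
class PsoConfig:
    """DMS-PSO settings.

    Defaults follow common DMS-PSO practice: linearly decreasing inertia
    0.9 → 0.4, c1 = c2 = 1.49445, 20 particles in 4 sub-swarms, regrouping
    every 5 iterations, velocity cap 0.2 × range per dimension, and early
    stop after ``patience`` iterations without global-best improvement.
    """

    bounds: Sequence[tuple[float, float]]
    n_particles: int = 20
    n_subswarms: int = 4
    inertia: float | tuple[float, float] = (0.9, 0.4)
    c1: float = 1.49445
    c2: float = 1.49445
    regroup_period: float | None = 5
    max_iter: int = 150
    patience: int | None = 20
    v_max: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_subswarms < 1:
            raise ValueError("n_particles and n_subswarms must be positive")
        if self.n_particles % self.n_subswarms != 0:
            raise ValueError("n_particles must be divisible by n_subswarms")
        if self.regroup_period is not None and self.regroup_period < 1:
            raise ValueError("regroup_period must be >= 1 (or None to disable)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): need lo < hi")

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)

    def velocity_cap(self) -> np.ndarray:
        if self.v_max is not None:
            return np.asarray(self.v_max, dtype=float)
        return 0.2 * (self.hi - self.lo)

    def inertia_at(self, t: int) -> float:
        if isinstance(self.inertia, (int, float)):
            return float(self.inertia)
        w0, w1 = self.inertia
        frac = min(t / max(self.max_iter, 1), 1.0)
        return w0 + (w1 - w0) * frac


@dataclass
class SwarmState:
    positions: np.ndarray  # (n, d)
    velocities: np.ndarray
    fitness: np.ndarray  # (n,)
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    subswarm: np.ndarray  # (n,) sub-swarm index per particle
    lbest_pos: np.ndarray  # (n_subswarms, d)
    lbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    t: int
    rng: np.random.Generator


@dataclass
class OptimizeResult:
    position: np.ndarray
    fitness: float
    history: list[float] = field(default_factory=list)
    n_iter: int = 0


def _evaluate(fitness_fn: Callable, positions: np.ndarray) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        try:
            v = float(fitness_fn(x))
        except FloatingPointError:
            v = math.inf
        out[i] = v if math.isfinite(v) else math.inf
    return out


def _local_bests(state: SwarmState, n_subswarms: int) -> None:
    for j in range(n_subswarms):
        members = np.flatnonzero(state.subswarm == j)
        best = members[np.argmin(state.pbest_fit[members])]
        state.lbest_pos[j] = state.pbest_pos[best]
        state.lbest_fit[j] = state.pbest_fit[best]


def init_swarm(config: PsoConfig, fitness_fn: Callable, rng: np.random.Generator | None = None) -> SwarmState:
    """Uniform random positions in bounds, velocities in ±v_max; pbest at
    the initial position; sub-swarms assigned by random permutation."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, d = config.n_particles, len(config.bounds)
    lo, hi = config.lo, config.hi
    vcap = config.velocity_cap()
    pos = lo + rng.random((n, d)) * (hi - lo)
    vel = (2.0 * rng.random((n, d)) - 1.0) * vcap
    fit = _evaluate(fitness_fn, pos)
    sub = np.empty(n, dtype=int)
    sub[rng.permutation(n)] = np.arange(n) % config.n_subswarms
    state = SwarmState(
        positions=pos,
        velocities=vel,
        fitness=fit,
        pbest_pos=pos.copy(),
        pbest_fit=fit.copy(),
        subswarm=sub,
        lbest_pos=np.zeros((config.n_subswarms, d)),
        lbest_fit=np.full(config.n_subswarms, math.inf),
        gbest_pos=pos[int(np.argmin(fit))].copy(),
        gbest_fit=float(np.min(fit)),
        t=0,
        rng=rng,
    )
    _local_bests(state, config.n_subswarms)
    return state


def step(state: SwarmState, fitness_fn: Callable, config: PsoConfig) -> SwarmState:
    """One synchronous velocity/position/fitness update.

    Fresh uniform r1, r2 are drawn per particle and dimension; velocities
    are capped at ±v_max, positions clamped to the bounds, and pbest/lbest
    updated only on strict improvement.
    """
    n, d = state.positions.shape
    lo, hi = config.lo, config.hi
    vcap = config.velocity_cap()
    omega = config.inertia_at(state.t)
    r1 = state.rng.random((n, d))
    r2 = state.rng.random((n, d))
    lbest_of = state.lbest_pos[state.subswarm]
    vel = (
        omega * state.velocities
        + config.c1 * r1 * (state.pbest_pos - state.positions)
        + config.c2 * r2 * (lbest_of - state.positions)
    )
    vel = np.clip(vel, -vcap, vcap)
    pos = np.clip(state.positions + vel, lo, hi)
    fit = _evaluate(fitness_fn, pos)

    state.velocities = vel
    state.positions = pos
    state.fitness = fit
    improved = fit < state.pbest_fit
    state.pbest_pos[improved] = pos[improved]
    state.pbest_fit[improved] = fit[improved]
    _local_bests(state, config.n_subswarms)
    best = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[best] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[best])
        state.gbest_pos = state.pbest_pos[best].copy()
    state.t += 1
    return state


def regroup(state: SwarmState, config: PsoConfig) -> SwarmState:
    """Randomly reassign all particles to equal-size sub-swarms.

    Personal bests and the global best are untouched; local bests are
    recomputed from the new memberships.
    """
    n = state.positions.shape[0]
    perm = state.rng.permutation(n)
    state.subswarm[perm] = np.arange(n) % config.n_subswarms
    _local_bests(state, config.n_subswarms)
    return state


def optimize(
    fitness_fn: Callable,
    config: PsoConfig,
    rng: np.random.Generator | None = None,
    callback: Callable | None = None,
) -> OptimizeResult:
    """Run DMS-PSO to minimise ``fitness_fn`` over the configured box.

    Returns the best-ever position and fitness plus the per-iteration
    best-so-far trace (monotone nonincreasing by construction). Stops at
    ``max_iter`` or after ``patience`` iterations without improvement.
    """
    state = init_swarm(config, fitness_fn, rng=rng)
    history: list[float] = []
    stall = 0
    for t in range(1, config.max_iter + 1):
        prev_best = state.gbest_fit
        step(state, fitness_fn, config)
        if (
            config.regroup_period is not None
            and math.isfinite(config.regroup_period)
            and state.t % int(config.regroup_period) == 0
        ):
            regroup(state, config)
        history.append(state.gbest_fit)
        if callback is not None:
            callback(state)
        if state.gbest_fit < prev_best:
            stall = 0
        else:
            stall += 1
        if config.patience is not None and stall >= config.patience:
            break
    return OptimizeResult(
        position=state.gbest_pos.copy(),
        fitness=state.gbest_fit,
        history=history,
        n_iter=state.t,
    )
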