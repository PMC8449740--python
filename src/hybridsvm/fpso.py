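"""Fuzzy self-tuning particle swarm optimizer (minimization).

A standard global-best PSO in a box, except that inertia, social and
cognitive factors and the velocity clamps are recomputed for every particle
at every iteration by Sugeno inference over (a) its distance to the global
best and (b) its normalized fitness increment — no user-set PSO constants.

Conventions: the swarm minimizes; callers maximizing an accuracy pass
``1 - accuracy``.  Swarm size follows the population heuristic
``floor(10 + 2 * sqrt(M))`` for an M-dimensional problem.  Velocities start
at zero; walls are absorbing (positions clamped into the box with the
offending velocity component zeroed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fuzzy import FuzzyRuleBase, FuzzySettings, default_rulebase

__all__ = [
    "SearchSpace",
    "Particle",
    "SwarmState",
    "FPSOResult",
    "swarm_size",
    "particle_distance",
    "fitness_increment",
    "compute_particle_settings",
    "update_particle",
    "fpso_minimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box with per-dimension bounds."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower/upper must be equal-length 1-D bounds")
        if not np.all(hi > lo):
            raise ValueError("upper bound must exceed lower bound in every dimension")

    @property
    def M(self) -> int:
        return len(self.lower)

    @property
    def range(self) -> np.ndarray:
        return np.asarray(self.upper, float) - np.asarray(self.lower, float)

    @property
    def delta_max(self) -> float:
        """Euclidean diagonal of the box; normalizes inter-particle distances."""
        return float(np.linalg.norm(self.range))


def swarm_size(M: int) -> int:
    """Population heuristic ``floor(10 + 2 * sqrt(M))`` (12 particles at M=2)."""
    if M < 1:
        raise ValueError("dimension must be >= 1")
    return int(math.floor(10 + 2 * math.sqrt(M)))


def particle_distance(x_i: Sequence[float], x_j: Sequence[float]) -> float:
    """Euclidean distance between two particle positions."""
    a, b = np.asarray(x_i, float), np.asarray(x_j, float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a - b))


def fitness_increment(step: float, delta_max: float, f_prev: float,
                      f_curr: float, f_wor: float) -> float:
    """Normalized fitness increment phi in [-1, 1].

    ``(step / delta_max) * (min(f_curr, f_wor) - min(f_prev, f_wor)) / f_wor``;
    negative values mean the particle improved.  With a zero worst fitness
    (every evaluation was perfect) the increment is defined as 0.
    """
    if f_wor <= 0:
        return 0.0
    if step < 0 or step > delta_max * (1 + 1e-9):
        raise ValueError("step must lie in [0, delta_max]")
    return (step / delta_max) * (min(f_curr, f_wor) - min(f_prev, f_wor)) / f_wor


@dataclass
class Particle:
    """Position, velocity and memory of one swarm member."""

    position: np.ndarray
    velocity: np.ndarray
    best: np.ndarray
    best_fitness: float
    fitness: float
    prev_position: np.ndarray | None = None
    prev_fitness: float | None = None
    settings: FuzzySettings | None = None


@dataclass
class SwarmState:
    """The whole swarm plus global bookkeeping."""

    particles: list[Particle]
    space: SearchSpace
    global_best: np.ndarray
    global_best_fitness: float
    worst_fitness: float
    iteration: int = 0


def compute_particle_settings(p: Particle, s: SwarmState,
                              rb: FuzzyRuleBase) -> FuzzySettings:
    """Defuzzified coefficients for ``p`` at the current iteration.

    delta is the particle's distance to the global best; phi is its
    normalized fitness increment over its last move, defined as 0 on the
    first iteration (no previous position).
    """
    delta = min(particle_distance(p.position, s.global_best), s.space.delta_max)
    if p.prev_position is None:
        phi = 0.0
    else:
        step = min(particle_distance(p.position, p.prev_position),
                   s.space.delta_max)
        phi = fitness_increment(step, s.space.delta_max, p.prev_fitness,
                                p.fitness, s.worst_fitness)
    return rb.infer(delta, s.space.delta_max, phi)


def update_particle(p: Particle, g: np.ndarray, space: SearchSpace,
                    rng: np.random.Generator, repel: bool = False) -> None:
    """One velocity/position update with per-dimension clamping, in place.

    ``v' = w v + c_soc r1 (g - x) + c_cog r2 (b - x)`` with fresh uniform
    r1, r2 per dimension; |v'| is clamped into [lam * range, eta * range]
    preserving sign (zero components stay zero — there is no sign to give
    the minimum-velocity floor); positions are clamped into the box and the
    offending velocity component zeroed.  ``repel=True`` flips the two
    attraction terms to the literal (x - g), (x - b) form, kept only for
    side-by-side comparison.
    """
    if p.settings is None:
        raise RuntimeError("particle settings not computed for this iteration")
    st = p.settings
    r1 = rng.uniform(size=space.M)
    r2 = rng.uniform(size=space.M)
    sign = -1.0 if repel else 1.0
    v = (st.w * p.velocity
         + st.c_soc * r1 * sign * (g - p.position)
         + st.c_cog * r2 * sign * (p.best - p.position))
    v_max = st.eta * space.range
    v_min = st.lam * space.range
    mag = np.abs(v)
    sgn = np.sign(v)
    mag = np.clip(mag, None, v_max)
    nonzero = mag > 0
    mag = np.where(nonzero, np.maximum(mag, v_min), 0.0)
    v = sgn * mag
    x = p.position + v
    lo = np.asarray(space.lower, float)
    hi = np.asarray(space.upper, float)
    hit = (x < lo) | (x > hi)
    x = np.clip(x, lo, hi)
    v = np.where(hit, 0.0, v)
    p.prev_position = p.position
    p.prev_fitness = p.fitness
    p.position = x
    p.velocity = v


@dataclass
class FPSOResult:
    """Best point/fitness and the per-iteration global-best trace."""

    best_position: np.ndarray
    best_fitness: float
    trace: list[dict] = field(default_factory=list)

    def trace_fitness(self) -> np.ndarray:
        return np.array([t["best_fitness"] for t in self.trace])


def fpso_minimize(objective: Callable[[np.ndarray], float], space: SearchSpace,
                  max_iter: int = 30, seed: int = 0,
                  rulebase: FuzzyRuleBase | None = None,
                  repel: bool = False) -> FPSOResult:
    """Minimize ``objective`` over the box; deterministic given ``seed``.

    The trace has one record per iteration (iteration index, global best
    fitness and position) and the best-fitness column is monotone
    non-increasing.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rb = rulebase if rulebase is not None else default_rulebase()
    rng = np.random.default_rng(seed)
    n = swarm_size(space.M)
    lo = np.asarray(space.lower, float)
    hi = np.asarray(space.upper, float)

    particles: list[Particle] = []
    for _ in range(n):
        x = rng.uniform(lo, hi)
        f = float(objective(x))
        particles.append(Particle(position=x, velocity=np.zeros(space.M),
                                  best=x.copy(), best_fitness=f, fitness=f))
    best_i = min(range(n), key=lambda i: particles[i].best_fitness)
    state = SwarmState(
        particles=particles, space=space,
        global_best=particles[best_i].best.copy(),
        global_best_fitness=particles[best_i].best_fitness,
        worst_fitness=max(p.fitness for p in particles))

    trace: list[dict] = []
    for k in range(1, max_iter + 1):
        state.iteration = k
        for p in particles:
            p.settings = compute_particle_settings(p, state, rb)
        for p in particles:
            update_particle(p, state.global_best, space, rng, repel=repel)
            p.fitness = float(objective(p.position))
            state.worst_fitness = max(state.worst_fitness, p.fitness)
            if p.fitness < p.best_fitness:
                p.best_fitness = p.fitness
                p.best = p.position.copy()
                if p.fitness < state.global_best_fitness:
                    state.global_best_fitness = p.fitness
                    state.global_best = p.position.copy()
        trace.append({"iteration": k,
                      "best_fitness": state.global_best_fitness,
                      "best_position": state.global_best.copy()})
    return FPSOResult(state.global_best, state.global_best_fitness, trace)
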