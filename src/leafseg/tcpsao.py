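"""Tent-chaotic particle-swarm snow-ablation optimizer (TCPSAO).

A bound-constrained population minimizer hybridizing three ingredients:

* **Tent-chaotic initialization** — the uniform random start population is
  passed once through the tent map ``F(x) = x/a`` for ``x < a`` else
  ``(1-x)/(1-a)``, whose invariant density at ``a = 0.5`` is uniform, to
  diversify the initial solutions;
* **Snow-ablation dynamics** — the population is split into an exploration
  subpopulation guided by a randomly drawn elite (global best, second best,
  third best, or centroid of the top half) perturbed by a Brownian
  (standard-normal) vector, and an exploitation subpopulation contracted
  toward personal bests by the iteration-dependent melting rate

      M(h) = (0.35 + 0.25 * (e^{h/h_max} - 1)/(e - 1)) * e^{-h/h_max};

  the exploitation share shrinks linearly over the run;
* **PSO velocity fusion** — a constriction-form particle-swarm velocity
  term (chi = 0.729, c1 = c2 = 1.49445), recomputed each iteration at the
  proposed position, is added to every position update.

``optimize`` also exposes the ``sao`` ablation (no tent pass, no velocity
term) and a canonical ``pso`` variant for comparison harnesses.  All
randomness flows from a single seeded generator, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "OptimizerConfig",
    "SwarmState",
    "OptimizeResult",
    "tent_map",
    "tent_iterates",
    "init_population",
    "melting_rate",
    "select_elite",
    "step",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class OptimizerConfig:
    """Population size, bounds, iteration budget and coefficients.

    ``lb``/``ub`` broadcast to per-dimension arrays of length ``dim``.
    ``alpha`` is the tent-map break point (0.5 gives a uniform invariant
    density); ``inertia``/``cognitive``/``social`` are the canonical PSO
    constriction coefficients.
    """

    n_particles: int
    dim: int
    h_max: int
    lb: np.ndarray
    ub: np.ndarray
    alpha: float = 0.5
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 4:
            raise ValueError("population size must be at least 4")
        if self.h_max < 1:
            raise ValueError("h_max must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if not (lb < ub).all():
            raise ValueError("require lb < ub element-wise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)


@dataclass
class SwarmState:
    """Mutable optimizer state: positions, velocities, fitness bookkeeping.

    ``pbest``/``pbest_f`` are personal bests O_i; ``gbest``/``gbest_f`` the
    global best O(h).  ``index_a``/``index_b`` partition the rows into the
    exploration and exploitation subpopulations for the current iteration.
    """

    positions: np.ndarray
    velocities: np.ndarray
    fitness: np.ndarray
    pbest: np.ndarray
    pbest_f: np.ndarray
    gbest: np.ndarray
    gbest_f: float
    iteration: int = 0
    index_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    index_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def mean_position(self) -> np.ndarray:
        """Population mean (the X-bar term of the update rules)."""
        return self.positions.mean(axis=0)

    def ranked(self) -> np.ndarray:
        """Row indices sorted by current fitness, best first (stable)."""
        return np.argsort(self.fitness, kind="stable")

    def leaders_centroid(self) -> np.ndarray:
        """Centroid X_C of the top half of the population by fitness rank."""
        n1 = max(1, len(self.fitness) // 2)
        return self.positions[self.ranked()[:n1]].mean(axis=0)


@dataclass(frozen=True)
class OptimizeResult:
    """Best-ever solution, its objective value, per-iteration history and
    the number of objective evaluations."""

    x: np.ndarray
    fun: float
    history: np.ndarray
    nfev: int


def tent_map(x: np.ndarray | float, alpha: float = 0.5) -> np.ndarray | float:
    """Parametric tent map on the unit interval.

    F(x) = x/alpha for x < alpha, (1-x)/(1-alpha) otherwise; maps [0, 1]
    onto itself with a uniform invariant density when alpha = 0.5.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly in (0, 1)")
    arr = np.asarray(x, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("tent map input must lie in [0, 1]")
    out = np.where(arr < alpha, arr / alpha, (1.0 - arr) / (1.0 - alpha))
    return float(out) if np.isscalar(x) else out


def tent_iterates(
    x0: float,
    n: int,
    alpha: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Chained tent-map orbit of length ``n`` starting from ``x0``.

    In double precision the orbit at alpha = 0.5 loses one mantissa bit per
    step and collapses onto the fixed point 0 after ~50 iterations; whenever
    the iterate degenerates to an endpoint the orbit is reseeded from the
    supplied random generator, preserving the uniform marginal distribution.
    """
    rng = np.random.default_rng(rng)
    out = np.empty(n)
    x = float(x0)
    for i in range(n):
        x = tent_map(x, alpha)
        if x <= 1e-12 or x >= 1.0 - 1e-12:
            x = float(rng.random())
        out[i] = x
    return out


def init_population(
    cfg: OptimizerConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Tent-chaotic initial population: uniform draw, one tent pass, affine
    map into [lb, ub].  All outputs lie within bounds."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x = cfg.lb + rng.random((cfg.n_particles, cfg.dim)) * (cfg.ub - cfg.lb)
    t = (x - cfg.lb) / (cfg.ub - cfg.lb)
    t = tent_map(t, cfg.alpha)
    return cfg.lb + t * (cfg.ub - cfg.lb)


def melting_rate(h: int, h_max: int) -> float:
    """Melting rate M(h) controlling exploitation contraction.

    M = (0.35 + 0.25 * (e^{h/h_max} - 1)/(e - 1)) * e^{-h/h_max}; equals
    0.35 at h = 0 and 0.6/e at h = h_max, positive throughout.
    """
    if not 0 <= h <= h_max:
        raise ValueError(f"iteration {h} outside [0, {h_max}]")
    ratio = h / h_max
    return (0.35 + 0.25 * (np.e**ratio - 1.0) / (np.e - 1.0)) * float(np.exp(-ratio))


def select_elite(state: SwarmState, rng: np.random.Generator) -> np.ndarray:
    """Draw the exploration guide uniformly from the elite pool
    {global best, second best, third best, centroid of the top half}."""
    ranked = state.ranked()
    pool = [
        state.gbest,
        state.positions[ranked[min(1, len(ranked) - 1)]],
        state.positions[ranked[min(2, len(ranked) - 1)]],
        state.leaders_centroid(),
    ]
    return np.array(pool[int(rng.integers(4))], copy=True)


def _evaluate(objective: Objective, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(row)) for row in positions])
    if not np.isfinite(vals).all():
        bad = positions[int(np.flatnonzero(~np.isfinite(vals))[0])]
        raise FloatingPointError(f"objective returned a non-finite value at {bad}")
    return vals


def make_state(objective: Objective, positions: np.ndarray) -> SwarmState:
    """Build a consistent SwarmState from an evaluated initial population."""
    fitness = _evaluate(objective, positions)
    best = int(fitness.argmin())
    return SwarmState(
        positions=positions.copy(),
        velocities=np.zeros_like(positions),
        fitness=fitness,
        pbest=positions.copy(),
        pbest_f=fitness.copy(),
        gbest=positions[best].copy(),
        gbest_f=float(fitness[best]),
    )


def _subpopulation_split(
    n: int, h: int, h_max: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random partition into exploration (a) and exploitation (b) index sets;
    the exploitation share N_b shrinks linearly from N/2 to 1."""
    n_b = max(1, round((n / 2) * (1.0 - h / h_max)))
    perm = rng.permutation(n)
    return perm[n_b:], perm[:n_b]


def step(
    state: SwarmState,
    objective: Objective,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    use_velocity: bool = True,
) -> SwarmState:
    """One TCPSAO iteration, in place.

    Exploration rows move toward a random elite with Brownian perturbation
    of the personal-best and population-mean displacements; exploitation
    rows contract toward their personal bests at the melting rate.  A PSO
    velocity term is then added (unless ``use_velocity`` is off, the SAO
    ablation), positions are clamped to the bounds, and personal/global
    bests are updated, so the global best never worsens.
    """
    n, dim = state.positions.shape
    h = state.iteration
    index_a, index_b = _subpopulation_split(n, h, cfg.h_max, rng)
    state.index_a, state.index_b = index_a, index_b

    xbar = state.mean_position
    m_rate = melting_rate(h, cfg.h_max)
    x_new = np.empty_like(state.positions)

    for i in index_a:
        elite = select_elite(state, rng)
        rb = rng.standard_normal(dim)
        r1 = rng.random()
        x_new[i] = elite + rb * (
            r1 * (state.pbest[i] - state.positions[i])
            + (1.0 - r1) * (xbar - state.positions[i])
        )
    for i in index_b:
        rb = rng.standard_normal(dim)
        r2 = rng.uniform(-1.0, 1.0)
        x_new[i] = m_rate * state.pbest[i] + rb * (
            r2 * (state.pbest[i] - state.positions[i])
            + (1.0 - r2) * (xbar - state.positions[i])
        )

    if use_velocity:
        # The velocity is recomputed each iteration at the proposal it is
        # applied to (constriction factor x cognitive/social pulls): an
        # inertia-carried velocity has no meaning when the base position is
        # regenerated by the ablation dynamics every step, and accumulating
        # it turns the update into an amplified random walk.
        u1 = rng.random((n, dim))
        u2 = rng.random((n, dim))
        state.velocities = cfg.inertia * (
            cfg.cognitive * u1 * (state.pbest - x_new)
            + cfg.social * u2 * (state.gbest - x_new)
        )
        x_new = x_new + state.velocities

    state.positions = np.clip(x_new, cfg.lb, cfg.ub)
    state.fitness = _evaluate(objective, state.positions)

    improved = state.fitness < state.pbest_f
    state.pbest[improved] = state.positions[improved]
    state.pbest_f[improved] = state.fitness[improved]
    best = int(state.pbest_f.argmin())
    if state.pbest_f[best] < state.gbest_f:
        state.gbest = state.pbest[best].copy()
        state.gbest_f = float(state.pbest_f[best])
    state.iteration += 1
    return state


def _pso_step(
    state: SwarmState, objective: Objective, cfg: OptimizerConfig, rng: np.random.Generator
) -> SwarmState:
    """Canonical constriction-form PSO iteration (comparison variant)."""
    n, dim = state.positions.shape
    u1 = rng.random((n, dim))
    u2 = rng.random((n, dim))
    state.velocities = (
        cfg.inertia * state.velocities
        + cfg.cognitive * u1 * (state.pbest - state.positions)
        + cfg.social * u2 * (state.gbest - state.positions)
    )
    state.positions = np.clip(state.positions + state.velocities, cfg.lb, cfg.ub)
    state.fitness = _evaluate(objective, state.positions)
    improved = state.fitness < state.pbest_f
    state.pbest[improved] = state.positions[improved]
    state.pbest_f[improved] = state.fitness[improved]
    best = int(state.pbest_f.argmin())
    if state.pbest_f[best] < state.gbest_f:
        state.gbest = state.pbest[best].copy()
        state.gbest_f = float(state.pbest_f[best])
    state.iteration += 1
    return state


def optimize(
    objective: Objective,
    cfg: OptimizerConfig,
    variant: str = "tcpsao",
) -> OptimizeResult:
    """Minimize ``objective`` over the box [lb, ub].

    variant ``"tcpsao"``: tent-chaotic init + SAO dynamics + PSO velocity;
    ``"sao"``: uniform init, SAO dynamics only (no velocity term);
    ``"pso"``: canonical particle swarm.  Returns the best-ever solution and
    a non-increasing best-fitness history of length ``h_max``.
    """
    if variant not in ("tcpsao", "sao", "pso"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(cfg.seed)
    if variant == "tcpsao":
        positions = init_population(cfg, rng)
    else:
        positions = cfg.lb + rng.random((cfg.n_particles, cfg.dim)) * (cfg.ub - cfg.lb)
    state = make_state(objective, positions)
    nfev = cfg.n_particles
    history = np.empty(cfg.h_max)
    for h in range(cfg.h_max):
        if variant == "pso":
            _pso_step(state, objective, cfg, rng)
        else:
            step(state, objective, cfg, rng, use_velocity=(variant == "tcpsao"))
        nfev += cfg.n_particles
        history[h] = state.gbest_f
    return OptimizeResult(
        x=state.gbest.copy(), fun=state.gbest_f, history=history, nfev=nfev
    )
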