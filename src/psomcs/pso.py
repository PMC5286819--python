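"""Particle swarm over design-threshold space.

Each particle is a vector of yield thresholds.  Evaluating a particle
builds the target/desired regions for its position, solves the cut-set
MILP and scores the result with a fitness rewarding high thresholds and
few knockouts:

    F(x) = (1 - |cMCS| / n) * prod_i x_i / x_i(max)

Velocities follow the constriction-coefficient update with a ring of four
fixed informants plus one random informant per iteration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import dual as dual_mod
from .design import DesignSpec, build_intervention
from .dual import BudgetExceeded, CutSet
from .lp import yield_bounds

log = logging.getLogger(__name__)


@dataclass
class PSOConfig:
    chi: float = 0.7298
    phi1: float = 2.0
    phi2: float = 2.0
    n_particles: int = 10
    max_iterations: int = 40
    stagnation_window: int = 10
    seed: int = 0
    max_cardinality: int = 5
    big_m: float = dual_mod.BIG_M
    milp_time_limit: float = None

    def __post_init__(self):
        if not 0 < self.chi < 1:
            raise ValueError("chi must lie in (0, 1)")
        if self.phi1 <= 0 or self.phi2 <= 0:
            raise ValueError("acceleration constants must be positive")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    p: np.ndarray
    p_fitness: float
    informants: list  # four fixed ring neighbours (indices)
    cutset: CutSet = None
    fitness: float = 0.0
    p_cutset: CutSet = None


@dataclass
class DesignResult:
    g: np.ndarray
    g_fitness: float
    best_cutset: CutSet
    fitness_trace: list
    evaluations: list  # (x tuple, sorted cut list or None, fitness)
    iterations_run: int
    bounds: list  # per-dimension (min, max)

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.g],
            "best_fitness": float(self.g_fitness),
            "best_cutset": self.best_cutset.sorted() if self.best_cutset else None,
            "fitness_trace": [float(v) for v in self.fitness_trace],
            "iterations_run": self.iterations_run,
            "bounds": [[float(a), float(b)] for a, b in self.bounds],
            "n_evaluations": len(self.evaluations),
        }


def fitness(x, cs, x_max, n: int) -> float:
    """Fitness of a design point given its cut set (or ``None`` when the
    MILP was infeasible)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x_max = np.atleast_1d(np.asarray(x_max, dtype=float))
    if np.any(x_max <= 0):
        raise ValueError("degenerate objective: x_max must be positive")
    if cs is None or cs.valid is False:
        return 0.0
    return float((1.0 - cs.cardinality / n) * np.prod(x / x_max))


def update_velocity(part: Particle, g, cfg: PSOConfig, rng) -> np.ndarray:
    """Constriction-coefficient velocity update; beta draws are uniform in
    (0, 1] per dimension."""
    b1 = 1.0 - rng.random(part.x.shape)
    b2 = 1.0 - rng.random(part.x.shape)
    return cfg.chi * (
        part.v
        + cfg.phi1 * b1 * (part.p - part.x)
        + cfg.phi2 * b2 * (np.asarray(g) - part.x)
    )


def update_position(part: Particle, bounds) -> np.ndarray:
    """``x <- x + v`` clamped to bounds; clamped dimensions zero their
    velocity so particles do not press against the walls."""
    x = part.x + part.v
    for i, (lo, hi) in enumerate(bounds):
        if x[i] < lo:
            x[i] = lo
            part.v[i] = 0.0
        elif x[i] > hi:
            x[i] = hi
            part.v[i] = 0.0
    return x


def evaluate_position(x, spec: DesignSpec, net, cfg: PSOConfig, x_max,
                      tie_break: str = "solver"):
    """Build regions, solve the cut-set MILP and score one position.

    Returns ``(CutSet | None, fitness)``.  MILP infeasibility (the desired
    region is empty or no cut set within the cap exists) and solver budget
    overruns both score 0.
    """
    problem = build_intervention(spec, x, net)
    system = dual_mod.build_dual(net, problem, cfg.max_cardinality, big_m=cfg.big_m)
    t0 = time.perf_counter()
    try:
        cs = dual_mod.solve_cmcs(system, tie_break=tie_break,
                                 time_limit=cfg.milp_time_limit)
    except BudgetExceeded:
        log.warning("MILP budget exceeded at x=%s", np.round(x, 6))
        return None, 0.0
    elapsed = time.perf_counter() - t0
    if cs is None:
        log.info("MILP x=%s status=infeasible wall=%.3fs", np.round(x, 6), elapsed)
        return None, 0.0
    dual_mod.validate_cutset(net, problem, cs)
    f = fitness(x, cs, x_max, net.n_reactions)
    log.info("MILP x=%s status=optimal |cMCS|=%d valid=%s fitness=%.6f wall=%.3fs",
             np.round(x, 6), cs.cardinality, cs.valid, f, elapsed)
    return cs, f


def _ring_informants(i: int, n_particles: int) -> list:
    return sorted({(i + d) % n_particles for d in (-2, -1, 1, 2)} - {i})


def run_pso(net, spec: DesignSpec, cfg: PSOConfig, bounds=None) -> DesignResult:
    """Run the swarm and return the best design found.

    Positions are initialized uniformly inside the FBA yield ranges,
    velocities uniformly in +/-(range).  The velocity guide is the best
    personal best among each particle's informants (ring of four plus one
    random informant per iteration, plus itself); the overall global best
    is tracked for reporting and stopping.  Stops at ``max_iterations`` or
    after ``stagnation_window`` iterations without improvement.
    """
    rng = np.random.default_rng(cfg.seed)
    if bounds is None:
        ranges = yield_bounds(net, spec.ratios())
        bounds = [(fr.min, fr.max) for fr in ranges]
    if len(bounds) != spec.j:
        raise ValueError("one (min, max) bound pair per dimension required")
    x_max = np.array([hi for _, hi in bounds])
    if np.any(x_max <= 0):
        raise ValueError("degenerate design: a maximal yield is not positive")

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo

    particles = []
    evaluations = []
    for i in range(cfg.n_particles):
        x = lo + rng.random(spec.j) * span
        v = -span + 2.0 * span * rng.random(spec.j)
        particles.append(
            Particle(x=x, v=v, p=x.copy(), p_fitness=-np.inf,
                     informants=_ring_informants(i, cfg.n_particles))
        )

    def evaluate(part: Particle):
        cs, f = evaluate_position(part.x, spec, net, cfg, x_max)
        part.cutset, part.fitness = cs, f
        evaluations.append((tuple(part.x), cs.sorted() if cs else None, f))
        if f > part.p_fitness:
            part.p_fitness = f
            part.p = part.x.copy()
            part.p_cutset = cs

    for part in particles:
        evaluate(part)

    def global_best():
        return max(particles, key=lambda p: p.p_fitness)

    best = global_best()
    g_fitness = best.p_fitness
    g = best.p.copy()
    g_cutset = best.p_cutset
    trace = [g_fitness]
    stagnant = 0
    iterations_run = 0

    for _ in range(cfg.max_iterations):
        iterations_run += 1
        # synchronous update: guides use last iteration's personal bests
        guides = []
        for i, part in enumerate(particles):
            others = list(part.informants)
            rand_inf = int(rng.integers(cfg.n_particles))
            if rand_inf != i and rand_inf not in others:
                others.append(rand_inf)
            pool = [particles[k] for k in others] + [part]
            guides.append(max(pool, key=lambda q: q.p_fitness).p.copy())
        for part, guide in zip(particles, guides):
            part.v = update_velocity(part, guide, cfg, rng)
            part.x = update_position(part, bounds)
        for part in particles:
            evaluate(part)
        best = global_best()
        if best.p_fitness > g_fitness + 1e-12:
            g_fitness = best.p_fitness
            g = best.p.copy()
            g_cutset = best.p_cutset
            stagnant = 0
        else:
            stagnant += 1
        trace.append(g_fitness)
        if stagnant >= cfg.stagnation_window:
            break

    # canonical deterministic re-solve at the reported optimum
    if g_fitness > 0:
        cs, f = evaluate_position(g, spec, net, cfg, x_max, tie_break="lex")
        if cs is not None and f >= g_fitness - 1e-9:
            g_cutset = cs

    return DesignResult(
        g=g,
        g_fitness=g_fitness,
        best_cutset=g_cutset,
        fitness_trace=trace,
        evaluations=evaluations,
        iterations_run=iterations_run,
        bounds=bounds,
    )
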