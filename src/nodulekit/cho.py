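"""Cnidaria Herd Optimization (CHO).

A bounded continuous metaheuristic that hybridises two swarm behaviours:
the passive, ocean-current drift of jellyfish (exploration) and the
density-seeking induced movement of krill (exploitation).  Which behaviour a
swarm member performs at iteration ``t`` is decided stochastically by a
time-control schedule ``zeta(t)`` that decays to zero as the iteration budget
is spent, so the swarm explores early and exploits late.  Candidate positions
that leave the box bounds are repaired by a diffusion-style wrap followed by
a clamp.

The optimizer maximises; wrap a minimisation objective with a negation.
All randomness flows through a single :class:`numpy.random.Generator`, so a
run is bit-reproducible from its seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Bounds",
    "CHOConfig",
    "SwarmState",
    "OptimizeResult",
    "init_swarm",
    "time_control",
    "differential_fitness",
    "exploration_step",
    "local_effect",
    "target_effect",
    "exploitation_step",
    "boundary_step",
    "optimize",
    "CHOOptimizer",
]


@dataclass(frozen=True)
class Bounds:
    """Box constraints: ``lower[j] < upper[j]`` per dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length >= 1")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def cube(cls, low: float, high: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(low)), np.full(dim, float(high)))


@dataclass(frozen=True)
class CHOConfig:
    """Tunables of the CHO run.

    Parameters
    ----------
    pop_size, t_max
        Swarm size and iteration budget.
    foraging_speed
        ``VF``, weight of the differential-fitness term in the exploration
        (foraging) move.
    trial_factor_scale
        The trial factor ``a`` is redrawn each move as
        ``trial_factor_scale * U(0, 1)``.
    sensitive_factor
        ``gamma``, magnitude of the random cooperative walk in the
        exploitation move, expressed as a fraction of the bound span.  The
        walk is additionally damped by ``(1 - t / t_max)`` so that it fades
        as the budget is spent, mirroring how the parent krill-herd operator
        anneals its physical diffusion.
    recursive_low, recursive_high
        Range of the recursive factor ``r3`` drawn per exploration move.
    diffusion_max
        ``D_max``, amplitude of the random diffusion added when an
        out-of-bounds coordinate is wrapped back into the box.
    epsilon
        Small positive constant guarding the normalised-displacement
        denominator.
    inertia_start, inertia_end
        Adaptive weightage factor shared by the exploration (``wF``) and
        exploitation (``wn``) moves; decays geometrically from start to end
        over the run.  The geometric schedule keeps the exploration
        multiplier contractive for most of the run, which is what gives the
        optimizer its late-stage precision.
    target_effect
        ``"best"`` adds a target-direction term pointing at the global best
        (krill-herd style); ``"zero"`` disables it.
    seed
        Seed for the run's private generator.
    """

    pop_size: int = 30
    t_max: int = 200
    foraging_speed: float = 0.02
    trial_factor_scale: float = 3.0
    sensitive_factor: float = 0.005
    recursive_low: float = 0.1
    recursive_high: float = 1.0
    diffusion_max: float = 0.005
    epsilon: float = 1e-10
    inertia_start: float = 0.9
    inertia_end: float = 0.01
    target_effect: str = "best"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.diffusion_max < 0:
            raise ValueError("diffusion_max must be >= 0")
        if not (0.0 < self.recursive_low <= self.recursive_high <= 1.0):
            raise ValueError("recursive factor range must lie within (0, 1]")
        if self.target_effect not in ("best", "zero"):
            raise ValueError("target_effect must be 'best' or 'zero'")

    def inertia(self, t: int) -> float:
        """Geometric decay from inertia_start to inertia_end over t in [1, t_max]."""
        if self.t_max == 1:
            return self.inertia_start
        frac = (t - 1) / (self.t_max - 1)
        lo = max(self.inertia_end, 1e-12)
        return float(self.inertia_start * (lo / self.inertia_start) ** frac)


@dataclass
class SwarmState:
    """Positions, fitnesses and elitist bookkeeping of the swarm.

    ``best_position``/``best_fitness`` are elitist (never overwritten by a
    worse candidate); ``worst_fitness`` is the minimum of the *current*
    fitnesses.
    """

    positions: np.ndarray
    previous_positions: np.ndarray
    fitnesses: np.ndarray
    previous_fitnesses: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    worst_fitness: float
    iteration: int
    rng: np.random.Generator = field(repr=False)

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray            # elitist best fitness after each iteration
    mean_history: np.ndarray       # mean swarm fitness after each iteration
    n_evaluations: int
    state: SwarmState


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    return np.array([float(objective(p)) for p in positions])


def init_swarm(bounds: Bounds, config: CHOConfig, objective) -> SwarmState:
    """Draw ``pop_size`` uniform positions in the box and evaluate them.

    Raises ``ValueError`` if the objective returns a non-finite value at any
    initial position.
    """
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(bounds.lower, bounds.upper, (config.pop_size, bounds.dim))
    fitnesses = _evaluate(objective, positions)
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("invalid objective: non-finite value at an initial position")
    gi = int(np.argmax(fitnesses))
    return SwarmState(
        positions=positions,
        previous_positions=positions.copy(),
        fitnesses=fitnesses,
        previous_fitnesses=fitnesses.copy(),
        best_position=positions[gi].copy(),
        best_fitness=float(fitnesses[gi]),
        worst_fitness=float(fitnesses.min()),
        iteration=0,
        rng=rng,
    )


def time_control(t: int, t_max: int, rng: np.random.Generator) -> float:
    """Time-control value ``zeta(t) = |(1 - t/t_max) * (2*r2 - 1)|`` in [0, 1].

    ``zeta`` decides the per-member phase: exploration when a fresh uniform
    draw exceeds ``1 - zeta``, exploitation otherwise.  ``zeta(t_max) == 0``
    exactly, so the final iteration is pure exploitation.
    """
    if t > t_max:
        raise ValueError("iteration overflow: t exceeds t_max")
    if t < 1:
        raise ValueError("t must be >= 1")
    r2 = rng.uniform()
    return abs((1.0 - t / t_max) * (2.0 * r2 - 1.0))


def differential_fitness(f_current: float, f_best: float) -> float:
    """``alpha_i = F(B_t) - F(BG)``; non-positive under elitist best tracking."""
    return float(f_current) - float(f_best)


def exploration_step(
    state: SwarmState, i: int, config: CHOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Foraging (ocean-current) move of member ``i``.

    ``B' = VF*alpha_i + wF*B + (B + r3*(BG - a*mu)) / 2`` with
    ``r3 ~ U(recursive range)`` and trial factor ``a = scale * U(0,1)``,
    both redrawn per call (draw order: r3 then a).
    """
    b = state.positions[i]
    alpha = differential_fitness(state.fitnesses[i], state.best_fitness)
    r3 = rng.uniform(config.recursive_low, config.recursive_high)
    a = config.trial_factor_scale * rng.uniform()
    w = config.inertia(max(state.iteration, 1))
    drift = state.best_position - a * state.mean_position
    return config.foraging_speed * alpha + w * b + (b + r3 * drift) / 2.0


def local_effect(state: SwarmState, i: int, config: CHOConfig) -> np.ndarray:
    """Neighbour-induced movement ``phi_local = sum_j Fhat_j * Bhat_j``.

    ``Fhat_j`` is member j's fitness change normalised by the swarm's
    current worst-to-best fitness range; ``Bhat_j`` is its displacement
    normalised by the sum of position norms.  A flat swarm (worst == best)
    carries no gradient information and yields the zero vector.
    """
    denom = state.worst_fitness - state.best_fitness
    if denom == 0.0:
        return np.zeros(state.dim)
    fhat = (state.fitnesses - state.previous_fitnesses) / denom
    norms = (
        np.linalg.norm(state.previous_positions, axis=1)
        + np.linalg.norm(state.positions, axis=1)
        + config.epsilon
    )
    bhat = (state.previous_positions - state.positions) / norms[:, None]
    return (fhat[:, None] * bhat).sum(axis=0)


def target_effect(state: SwarmState, i: int, config: CHOConfig) -> np.ndarray:
    """Target-direction term pointing member ``i`` at the global best.

    Uses the same normalised-fitness / normalised-displacement construction
    as :func:`local_effect`, with the global best standing in for the
    neighbour.  Disabled (zero vector) when ``config.target_effect == "zero"``
    or the swarm is fitness-flat.
    """
    if config.target_effect == "zero":
        return np.zeros(state.dim)
    denom = state.worst_fitness - state.best_fitness
    if denom == 0.0:
        return np.zeros(state.dim)
    fhat_g = (state.fitnesses[i] - state.best_fitness) / denom
    b = state.positions[i]
    bhat_g = (state.best_position - b) / (
        np.linalg.norm(state.best_position) + np.linalg.norm(b) + config.epsilon
    )
    return fhat_g * bhat_g


def exploitation_step(
    state: SwarmState,
    i: int,
    config: CHOConfig,
    rng: np.random.Generator,
    bounds: Bounds,
) -> np.ndarray:
    """Induced (krill-style) move of member ``i`` inside the swarm.

    ``B' = B + gamma*r4*(U_up - U_low)*(1 - t/t_max)
           + (BG . phi_B + wn*B_prev) / 2``
    with ``r4 ~ U(0,1)`` per dimension, ``phi_B = phi_local + phi_target``
    and ``.`` element-wise.  The random cooperative walk is damped linearly
    over the run (see :class:`CHOConfig`).
    """
    b = state.positions[i]
    r4 = rng.uniform(size=state.dim)
    t = max(state.iteration, 1)
    damp = 1.0 - t / config.t_max
    w = config.inertia(t)
    phi = local_effect(state, i, config) + target_effect(state, i, config)
    kick = config.sensitive_factor * r4 * bounds.span * damp
    return b + kick + (state.best_position * phi + w * state.previous_positions[i]) / 2.0


def boundary_step(
    position: np.ndarray, bounds: Bounds, config: CHOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Diffusion-style bounds repair.

    An out-of-bounds coordinate re-enters from the opposite face, displaced
    by its overshoot plus random diffusion ``D_max * U(-1, 1)``; a final
    clamp guarantees containment even for far-out points.
    """
    position = np.asarray(position, dtype=float)
    over = position > bounds.upper
    under = position < bounds.lower
    if not (over.any() or under.any()):
        return position.copy()
    delta = rng.uniform(-1.0, 1.0, size=position.shape)
    repaired = position.copy()
    repaired[over] = (
        position[over] - bounds.upper[over] + bounds.lower[over]
        + config.diffusion_max * delta[over]
    )
    repaired[under] = (
        position[under] - bounds.lower[under] + bounds.upper[under]
        + config.diffusion_max * delta[under]
    )
    return np.clip(repaired, bounds.lower, bounds.upper)


def optimize(
    objective,
    bounds: Bounds,
    config: CHOConfig,
    callback=None,
) -> OptimizeResult:
    """Run CHO for ``t_max`` iterations and return the elitist best.

    The per-iteration phase of each member is decided by the time-control
    rule; every candidate position is passed through :func:`boundary_step`
    before evaluation, so positions lie inside the bounds after every
    completed iteration.  A candidate whose fitness is non-finite is
    rejected (the member keeps its previous position) with a logged warning.

    ``callback(state)``, if given, is invoked after each completed
    iteration (used by tests to audit containment and by the CLI trace).
    """
    state = init_swarm(bounds, config, objective)
    rng = state.rng
    n_eval = config.pop_size
    history = np.empty(config.t_max)
    mean_history = np.empty(config.t_max)

    for t in range(1, config.t_max + 1):
        state.iteration = t
        zeta = time_control(t, config.t_max, rng)
        candidates = np.empty_like(state.positions)
        for i in range(config.pop_size):
            if rng.uniform() > 1.0 - zeta:
                cand = exploration_step(state, i, config, rng)
            else:
                cand = exploitation_step(state, i, config, rng, bounds)
            candidates[i] = boundary_step(cand, bounds, config, rng)

        new_fitnesses = _evaluate(objective, candidates)
        n_eval += config.pop_size
        bad = ~np.isfinite(new_fitnesses)
        if bad.any():
            logger.warning(
                "rejected %d candidate(s) with non-finite objective at iteration %d",
                int(bad.sum()), t,
            )
            candidates[bad] = state.positions[bad]
            new_fitnesses[bad] = state.fitnesses[bad]

        state.previous_positions = state.positions
        state.previous_fitnesses = state.fitnesses
        state.positions = candidates
        state.fitnesses = new_fitnesses
        gi = int(np.argmax(new_fitnesses))
        if new_fitnesses[gi] > state.best_fitness:
            state.best_fitness = float(new_fitnesses[gi])
            state.best_position = candidates[gi].copy()
        state.worst_fitness = float(new_fitnesses.min())
        history[t - 1] = state.best_fitness
        mean_history[t - 1] = float(new_fitnesses.mean())
        if callback is not None:
            callback(state)

    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=history,
        mean_history=mean_history,
        n_evaluations=n_eval,
        state=state,
    )


class CHOOptimizer:
    """Thin object wrapper bundling a config with :func:`optimize`.

    Convenient for passing a configured optimizer into model-training code;
    also writes an optional CSV trace (iteration, best_fitness,
    mean_fitness).
    """

    def __init__(self, config: CHOConfig | None = None, **overrides):
        base = config or CHOConfig()
        if overrides:
            from dataclasses import asdict, replace

            unknown = set(overrides) - set(asdict(base))
            if unknown:
                raise TypeError(f"unknown CHOConfig fields: {sorted(unknown)}")
            base = replace(base, **overrides)
        self.config = base

    def optimize(self, objective, bounds: Bounds, trace_path=None) -> OptimizeResult:
        result = optimize(objective, bounds, self.config)
        if trace_path is not None:
            import csv

            with open(trace_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["iteration", "best_fitness", "mean_fitness"])
                for t, (b, m) in enumerate(zip(result.history, result.mean_history), 1):
                    writer.writerow([t, repr(b), repr(m)])
        return result
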