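"""Stage 2: binary particle swarm optimization over the filtered gene pool.

Each particle carries a bit-vector over the D candidate genes (1 = gene
included) and a real velocity per bit. Velocities follow the canonical
update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)

with per-component uniform draws r1, r2 and a symmetric clamp at v_max;
positions are resampled through the sigmoid transfer: bit = 1 iff
u < 1/(1 + exp(-v)). The fitness being minimized trades classification
error against subset size,

    f(x) = alpha * Error(x) + beta * |x| / D

where Error(x) is the cross-validated misclassification rate of the
wrapped SVM on the included genes. Personal and global bests replace the
incumbent only on strict improvement, which makes the global-best trace
monotonically non-increasing by construction.

Positions that resample to all zeros are repaired by switching one
uniformly chosen bit on: an empty gene set has no defined classifier
error. The search stops at max_iter, or earlier after stall_iters
iterations without global-best improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .classifier_eval import ClassifierConfig, holdout_error, kfold_error
from .expression_io import ExpressionDataset, GeneSubset


@dataclass
class PSOConfig:
    """Swarm hyperparameters.

    Defaults follow the original binary-PSO formulation: 30 particles, 100
    iterations, no inertia damping (w=1), cognitive/social coefficients
    c1=c2=2, velocity clamp v_max=6 (sigmoid(6) ~= 0.9975 keeps every bit
    able to flip), initial inclusion probability 0.1 (biased toward the
    small subsets the method is meant to find), stall window 20 iterations.

    w=1 matters in the binary variant: positions are *resampled* through
    the sigmoid every iteration, so a damped velocity (w < ~0.9) reaches a
    pull/decay equilibrium well inside the clamp and settled bits keep
    flipping with non-trivial probability — the swarm never converges
    tightly. With w=1 velocities accumulate to saturation at +/-v_max and
    agreed bits freeze, which is what makes compact subsets reachable.
    """

    n_particles: int = 30
    max_iter: int = 100
    w: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    stall_iters: int = 20
    init_prob: float = 0.1
    target_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be >= 0")
        if not (0.0 < self.init_prob < 1.0):
            raise ValueError("init_prob must be in (0, 1)")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("target_size must be >= 1")


@dataclass
class FitnessConfig:
    """Objective weights and the error estimator wrapped inside fitness.

    alpha weighs the cross-validated error, beta the relative subset size
    |x|/D. D defaults to the pool size. The inner estimator defaults to
    stratified 5-fold CV; "loocv" restores one-sample folds for the search
    itself, "holdout" a single stratified 80/20 split.
    """

    alpha: float = 0.9
    beta: float = 0.1
    D: int | None = None
    error_estimator: str = "kfold"  # {"kfold", "loocv", "holdout"}
    n_folds: int = 5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")
        if self.error_estimator not in {"kfold", "loocv", "holdout"}:
            raise ValueError("error_estimator must be kfold, loocv or holdout")


@dataclass
class Particle:
    position: np.ndarray  # int8 bits, length D
    velocity: np.ndarray  # float, clamped to [-v_max, v_max]
    best_position: np.ndarray
    best_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    global_best_position: np.ndarray
    global_best_fitness: float
    iteration: int = 0


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_velocity(
    p: Particle, gbest: np.ndarray, cfg: PSOConfig, rng: np.random.Generator
) -> np.ndarray:
    """One velocity update with fresh per-component r1, r2 draws, clamped."""
    r1 = rng.random(p.position.shape[0])
    r2 = rng.random(p.position.shape[0])
    v = (
        cfg.w * p.velocity
        + cfg.c1 * r1 * (p.best_position - p.position)
        + cfg.c2 * r2 * (gbest - p.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(
    velocity: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sigmoid-transfer resampling of the bit vector, with empty repair."""
    bits = (rng.random(velocity.shape[0]) < sigmoid(velocity)).astype(np.int8)
    return _repair(bits, rng)


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits[rng.integers(bits.shape[0])] = 1
    return bits


def _resize_to_target(
    bits: np.ndarray, velocity: np.ndarray, target: int
) -> np.ndarray:
    """Force exactly `target` set bits, keeping the highest-velocity ones."""
    target = min(target, bits.shape[0])
    keep = np.argsort(-velocity, kind="stable")[:target]
    out = np.zeros_like(bits)
    out[keep] = 1
    return out


def update_bests(p: Particle, swarm: Swarm, fit: float) -> None:
    """Strict-improvement elitism for personal and global bests (ties keep
    the incumbent)."""
    if fit < p.best_fitness:
        p.best_fitness = fit
        p.best_position = p.position.copy()
    if fit < swarm.global_best_fitness:
        swarm.global_best_fitness = fit
        swarm.global_best_position = p.position.copy()


def optimize_bits(
    n_bits: int,
    fitness_fn: Callable[[np.ndarray], float],
    cfg: PSOConfig,
) -> tuple[np.ndarray, list[float]]:
    """Run the swarm on an arbitrary bit-vector objective.

    This is the engine behind optimize(); exposing it directly lets the
    search be exercised against analytic objectives with a known optimum.
    Returns the global best position and the per-iteration trace of the
    global best fitness (non-increasing). Fitness values are cached by bit
    pattern: revisited subsets cost nothing and results are unchanged.
    """
    if n_bits < 1:
        raise ValueError("need at least one candidate bit")
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def cached_fitness(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(bits))
        return cache[key]

    particles: list[Particle] = []
    for _ in range(cfg.n_particles):
        bits = (rng.random(n_bits) < cfg.init_prob).astype(np.int8)
        bits = _repair(bits, rng)
        vel = rng.uniform(-1.0, 1.0, size=n_bits)
        if cfg.target_size is not None:
            bits = _resize_to_target(bits, vel, cfg.target_size)
        particles.append(Particle(bits, vel, bits.copy(), np.inf))
    swarm = Swarm(particles, particles[0].position.copy(), np.inf)

    trace: list[float] = []
    stall = 0
    for it in range(cfg.max_iter):
        if it > 0:
            for p in swarm.particles:
                p.velocity = update_velocity(p, swarm.global_best_position, cfg, rng)
                bits = update_position(p.velocity, rng)
                if cfg.target_size is not None:
                    bits = _resize_to_target(bits, p.velocity, cfg.target_size)
                p.position = bits
        previous_best = swarm.global_best_fitness
        for p in swarm.particles:
            update_bests(p, swarm, cached_fitness(p.position))
        swarm.iteration = it + 1
        trace.append(swarm.global_best_fitness)
        stall = 0 if swarm.global_best_fitness < previous_best else stall + 1
        if stall >= cfg.stall_iters:
            break
    return swarm.global_best_position.copy(), trace


def fitness(
    position: np.ndarray,
    pool: GeneSubset,
    dataset: ExpressionDataset,
    cfg: FitnessConfig,
) -> float:
    """f(x) = alpha * Error(x) + beta * |x| / D for one bit vector."""
    position = np.asarray(position)
    if position.shape[0] != len(pool):
        raise ValueError("position length must equal pool size")
    if position.sum() == 0:
        raise ValueError("all-zero position must be repaired before evaluation")
    X_pool = dataset.subset_values(pool)
    return _make_objective(X_pool, dataset.labels, cfg)(position)


def _make_objective(
    X_pool: np.ndarray, y: np.ndarray, cfg: FitnessConfig
) -> Callable[[np.ndarray], float]:
    D = cfg.D if cfg.D is not None else X_pool.shape[1]

    def objective(bits: np.ndarray) -> float:
        X = X_pool[:, bits.astype(bool)]
        if cfg.alpha == 0.0:
            err = 0.0
        elif cfg.error_estimator == "kfold":
            err = kfold_error(X, y, cfg.classifier, cfg.n_folds, cfg.seed)
        elif cfg.error_estimator == "loocv":
            from sklearn.model_selection import LeaveOneOut

            from .classifier_eval import _cv_predictions

            preds, _, mask = _cv_predictions(X, y, cfg.classifier, LeaveOneOut())
            err = float((preds[mask] != y[mask]).mean())
        else:
            err = holdout_error(X, y, cfg.classifier, seed=cfg.seed)
        return cfg.alpha * err + cfg.beta * float(bits.sum()) / D

    return objective


def optimize(
    pool: GeneSubset,
    dataset: ExpressionDataset,
    pso_cfg: PSOConfig,
    fit_cfg: FitnessConfig,
) -> tuple[GeneSubset, list[float]]:
    """Search the filtered pool for the best gene subset.

    Bit i of every particle corresponds to pool.gene_ids[i]; the returned
    subset maps the set bits of the global best back to gene ids in pool
    order. The run is a pure function of (dataset, configs, seeds).
    """
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    X_pool = dataset.subset_values(pool)
    objective = _make_objective(X_pool, dataset.labels, fit_cfg)
    best_bits, trace = optimize_bits(len(pool), objective, pso_cfg)
    genes = [g for g, b in zip(pool.gene_ids, best_bits) if b]
    return GeneSubset(genes, source_stage="pso"), trace
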