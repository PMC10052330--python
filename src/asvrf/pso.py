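"""Particle swarm optimization with linearly decaying inertia.

A swarm of N_p particles explores a box-bounded D-dimensional space. Each
iteration updates particle velocities toward the particle's own best-ever
position (pbest) and the swarm's best-ever position (gbest),

    v <- w*v + c1*rand()*(pbest - x) + c2*rand()*(gbest - x)
    x <- x + v,

with the inertia weight w decayed linearly from w_max to w_min over the run
so the search starts global and ends local. Velocities are clamped to a
fraction of each dimension's range and positions are reflected back into
bounds. The module is a generic minimizer; :func:`tune_asvrf` wires it to
the forest's (beta, k) hyperparameters via cross-validated error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .forest import ForestConfig, forest_predict, train_asv_rf

__all__ = ["PSOConfig", "SwarmState", "inertia_weight", "step", "optimize", "tune_asvrf", "stratified_folds"]


@dataclass
class PSOConfig:
    bounds: list[tuple[float, float]] = field(default_factory=lambda: [(-5.0, 5.0)])
    n_particles: int = 30
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.9
    w_min: float = 0.4
    iter_max: int = 200
    clamp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("swarm needs at least 2 particles")
        if self.iter_max < 1:
            raise ValueError("iter_max must be at least 1")
        if self.w_max < self.w_min:
            raise ValueError("w_max must be >= w_min")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration constants must be positive")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy low < high")

    @property
    def dimensions(self) -> int:
        return len(self.bounds)


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_values: np.ndarray
    gbest_position: np.ndarray
    gbest_value: float
    iteration: int = 0


def inertia_weight(iteration: int, cfg: PSOConfig) -> float:
    """Linear decay: w_max at iteration 0, w_min at iter_max."""
    if not 0 <= iteration <= cfg.iter_max:
        raise ValueError(f"iteration must lie in [0, {cfg.iter_max}]")
    return cfg.w_max - (cfg.w_max - cfg.w_min) / cfg.iter_max * iteration


def _evaluate(objective, position: np.ndarray) -> float:
    value = float(objective(position))
    return value if np.isfinite(value) else np.inf


def init_swarm(objective, cfg: PSOConfig, rng: np.random.Generator) -> SwarmState:
    """Uniform-random positions, zero velocities, bests from the first sweep."""
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    positions = rng.uniform(lo, hi, size=(cfg.n_particles, cfg.dimensions))
    values = np.array([_evaluate(objective, p) for p in positions])
    best = int(np.argmin(values))
    return SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        pbest_positions=positions.copy(),
        pbest_values=values,
        gbest_position=positions[best].copy(),
        gbest_value=float(values[best]),
    )


def step(state: SwarmState, objective, cfg: PSOConfig, rng: np.random.Generator) -> SwarmState:
    """One synchronous swarm update (in place); returns the state."""
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    span = hi - lo
    vmax = cfg.clamp_fraction * span
    w = inertia_weight(state.iteration, cfg)
    r1 = rng.random(state.positions.shape)
    r2 = rng.random(state.positions.shape)
    v = (
        w * state.velocities
        + cfg.c1 * r1 * (state.pbest_positions - state.positions)
        + cfg.c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    np.clip(v, -vmax, vmax, out=v)
    x = state.positions + v
    # reflect out-of-bounds coordinates back inside (possibly repeatedly)
    for _ in range(64):
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            break
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
    np.clip(x, lo, hi, out=x)
    values = np.array([_evaluate(objective, p) for p in x])
    improved = values < state.pbest_values
    state.pbest_positions[improved] = x[improved]
    state.pbest_values[improved] = values[improved]
    best = int(np.argmin(state.pbest_values))
    if state.pbest_values[best] < state.gbest_value:
        state.gbest_value = float(state.pbest_values[best])
        state.gbest_position = state.pbest_positions[best].copy()
    state.positions = x
    state.velocities = v
    state.iteration += 1
    return state


def optimize(objective, cfg: PSOConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Run iter_max steps; returns (best position, best value, gbest trace)."""
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(objective, cfg, rng)
    trace = np.empty(cfg.iter_max + 1)
    trace[0] = state.gbest_value
    for i in range(cfg.iter_max):
        step(state, objective, cfg, rng)
        trace[i + 1] = state.gbest_value
    return state.gbest_position.copy(), state.gbest_value, trace


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Per-row fold assignment (0..folds-1) with class proportions preserved."""
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=np.int64)
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        if len(rows) < folds:
            raise ValueError(f"class {c} has {len(rows)} members, fewer than {folds} folds")
        rows = rng.permutation(rows)
        assignment[rows] = np.arange(len(rows)) % folds
    return assignment


def tune_asvrf(
    train: Dataset,
    beta_range: tuple[float, float] = (0.1, 1.0),
    k_range: tuple[int, int] = (5, 100),
    folds: int = 3,
    pso_cfg: PSOConfig | None = None,
    base_cfg: ForestConfig | None = None,
) -> tuple[ForestConfig, float]:
    """Tune (beta, k) by minimizing stratified cross-validated error.

    Particle positions live in continuous (beta, k) space; k is rounded and
    beta clipped at evaluation time. The fold assignment is drawn once, so
    the objective is a deterministic function of position. Returns the best
    decoded ForestConfig and its CV misclassification rate.
    """
    train.validate_for_training()
    base = base_cfg if base_cfg is not None else ForestConfig()

    def _padded(lo: float, hi: float) -> tuple[float, float]:
        # degenerate (single-point) search ranges still need a valid box
        if hi <= lo:
            hi = lo + max(1e-9, abs(lo) * 1e-9)
        return float(lo), float(hi)

    bounds = [_padded(*beta_range), _padded(float(k_range[0]), float(k_range[1]))]
    if pso_cfg is None:
        pso_cfg = PSOConfig(bounds=bounds, n_particles=6, iter_max=8)
    else:
        pso_cfg = PSOConfig(**{**pso_cfg.__dict__, "bounds": bounds})
    assignment = stratified_folds(train.labels, folds, seed=pso_cfg.seed)
    cache: dict[tuple[float, int], float] = {}

    def decode(position: np.ndarray) -> tuple[float, int]:
        beta = float(np.clip(position[0], max(beta_range[0], 1e-9), min(beta_range[1], 1.0)))
        k = int(np.clip(round(position[1]), k_range[0], k_range[1]))
        return beta, k

    def objective(position: np.ndarray) -> float:
        beta, k = decode(position)
        key = (round(beta, 6), k)
        if key not in cache:
            errors = []
            for fold in range(folds):
                tr = train.subset(np.flatnonzero(assignment != fold))
                te = train.subset(np.flatnonzero(assignment == fold))
                cfg = ForestConfig(**{**base.to_dict(), "beta": beta, "k": k,
                                      "tree": base.tree, "seed": base.seed})
                forest = train_asv_rf(tr, cfg)
                pred = forest_predict(forest, te.features)
                errors.append(float(np.mean(pred != te.labels)))
            cache[key] = float(np.mean(errors))
        return cache[key]

    position, value, _ = optimize(objective, pso_cfg)
    beta, k = decode(position)
    tuned = ForestConfig(**{**base.to_dict(), "beta": beta, "k": k, "tree": base.tree})
    return tuned, value
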