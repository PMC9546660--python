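"""Binary Particle Swarm Optimization wrapper feature selection.

Each particle carries a binary position x (a feature mask) and a real-valued
velocity v.  The velocity update is the classic PSO rule

    v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),

with r1, r2 fresh uniform(0,1) draws and componentwise clamping to
[-v_max, v_max].  The position is *resampled* through the sigmoid transfer
function S(v) = 1 / (1 + exp(-v)): coordinate d becomes 1 with probability
S(v_d), else 0.  Fitness is the misclassification rate of a k-nearest-
neighbour classifier on the masked feature columns, estimated on a stratified
internal holdout fixed for the whole run — lower is better, no feature-count
penalty.  Personal and global bests update only on strict improvement.

The inertia weight decays linearly from ``w_start`` to ``w_end`` over the
iteration budget, the usual exploration→exploitation schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .datasets import FeatureDataset

__all__ = [
    "BpsoConfig",
    "Particle",
    "SelectionResult",
    "sigmoid_transfer",
    "init_swarm",
    "update_velocity",
    "update_position",
    "fitness",
    "update_pbest_gbest",
    "bpso_select",
    "bpso_select_runs",
]


@dataclass(frozen=True)
class BpsoConfig:
    """BPSO hyperparameters.

    Defaults follow canonical BPSO practice: inertia decayed 0.9 → 0.4,
    cognitive and social coefficients 2.0, swarm of 20 for 100 iterations,
    velocities clamped to ±6 (beyond which the sigmoid saturates), kNN with
    k = 5 as the wrapper classifier.
    """

    swarm_size: int = 20
    max_iter: int = 100
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    knn_k: int = 5
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")

    def inertia(self, t: int) -> float:
        """Linearly decayed inertia weight at iteration t (0-based)."""
        if self.max_iter <= 1:
            return self.w_start
        frac = t / (self.max_iter - 1)
        return self.w_start + (self.w_end - self.w_start) * frac


@dataclass
class Particle:
    """One candidate feature mask with its velocity and personal best."""

    position: np.ndarray  # binary, length D
    velocity: np.ndarray  # real, length D, |v| <= v_max
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SelectionResult:
    """Outcome of a BPSO run: the global-best mask and its trajectory."""

    gbest_mask: np.ndarray
    gbest_fitness: float
    fitness_history: np.ndarray  # best-so-far per iteration, non-increasing
    n_selected: int = field(init=False)
    config: BpsoConfig | None = None

    def __post_init__(self) -> None:
        self.n_selected = int(self.gbest_mask.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.gbest_mask)


def sigmoid_transfer(v):
    """Logistic transfer S(v) = 1 / (1 + exp(-v)), elementwise."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out if out.ndim else float(out)


def _repair_empty(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero masks are invalid: set one uniformly random coordinate to 1."""
    if position.sum() == 0:
        position = position.copy()
        position[rng.integers(position.size)] = 1
    return position


class _HoldoutFitness:
    """kNN error-rate fitness on a stratified holdout fixed for one run.

    Deterministic within a run, so evaluations are memoised by mask bytes.
    """

    def __init__(self, data: FeatureDataset, cfg: BpsoConfig, rng: np.random.Generator):
        if len(np.unique(data.y)) < 2:
            raise ValueError("fitness requires both classes present")
        tr_idx, va_idx = _stratified_holdout_indices(
            data.y, cfg.validation_fraction, rng
        )
        self._Xtr, self._ytr = data.X[tr_idx], data.y[tr_idx]
        self._Xva, self._yva = data.X[va_idx], data.y[va_idx]
        self._k = min(cfg.knn_k, len(tr_idx))
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.packbits(mask.astype(np.uint8)).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            raise ValueError("fitness is undefined on an empty mask")
        knn = KNeighborsClassifier(n_neighbors=self._k, metric="euclidean")
        knn.fit(self._Xtr[:, cols], self._ytr)
        err = float(np.mean(knn.predict(self._Xva[:, cols]) != self._yva))
        self._cache[key] = err
        self.n_evaluations += 1
        return err


def _stratified_holdout_indices(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, round(len(idx) * val_fraction))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def fitness(mask: np.ndarray, data: FeatureDataset, cfg: BpsoConfig) -> float:
    """kNN misclassification rate of the masked features (lower is better).

    Stand-alone form: draws the stratified holdout from ``cfg.seed``.  Inside
    :func:`bpso_select` the holdout is drawn once per run instead.
    """
    rng = np.random.default_rng(cfg.seed)
    return _HoldoutFitness(data, cfg, rng)(np.asarray(mask))


def init_swarm(
    D: int, cfg: BpsoConfig, rng: np.random.Generator, fit=None
) -> list[Particle]:
    """Random initial swarm: fair-coin positions, uniform velocities.

    Empty initial masks are repaired.  When ``fit`` is given, pbest fitness
    is the evaluated initial fitness; otherwise it is +inf (unevaluated).
    """
    if D < 1:
        raise ValueError("dimensionality D must be >= 1")
    swarm = []
    for _ in range(cfg.swarm_size):
        pos = _repair_empty((rng.random(D) < 0.5).astype(np.int8), rng)
        vel = rng.uniform(-cfg.v_max, cfg.v_max, size=D)
        f = fit(pos) if fit is not None else np.inf
        swarm.append(Particle(pos, vel, pos.copy(), f))
    return swarm


def update_velocity(
    p: Particle, gbest: np.ndarray, cfg: BpsoConfig, rng: np.random.Generator,
    w: float | None = None,
) -> np.ndarray:
    """New clamped velocity from inertia, cognitive and social terms."""
    gbest = np.asarray(gbest)
    if gbest.shape != p.position.shape:
        raise ValueError("gbest dimension mismatch")
    if w is None:
        w = cfg.w_start
    r1 = rng.random(p.position.size)
    r2 = rng.random(p.position.size)
    v = (
        w * p.velocity
        + cfg.c1 * r1 * (p.pbest_position - p.position)
        + cfg.c2 * r2 * (gbest - p.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: Particle, rng: np.random.Generator) -> np.ndarray:
    """Resample the binary position: x_d = 1 iff rand < S(v_d)."""
    prob = sigmoid_transfer(p.velocity)
    return (rng.random(p.position.size) < prob).astype(np.int8)


def update_pbest_gbest(
    swarm: list[Particle],
    fitnesses: np.ndarray,
    gbest_position: np.ndarray,
    gbest_fitness: float,
) -> tuple[np.ndarray, float]:
    """Strict-improvement bookkeeping for personal and global bests.

    Ties keep the incumbent (strict '<' in both comparisons).  Mutates each
    particle's pbest in place; returns the updated gbest.
    """
    for p, f in zip(swarm, fitnesses):
        if f < p.pbest_fitness:
            p.pbest_fitness = float(f)
            p.pbest_position = p.position.copy()
    for p in swarm:
        if p.pbest_fitness < gbest_fitness:
            gbest_fitness = p.pbest_fitness
            gbest_position = p.pbest_position.copy()
    return gbest_position, gbest_fitness


def bpso_select(data: FeatureDataset, cfg: BpsoConfig) -> SelectionResult:
    """Run BPSO feature selection and return the global best mask.

    The loop is init → [velocity → position → fitness → pbest/gbest] × T;
    the recorded history is the best-so-far fitness after initialization and
    after each iteration (length T + 1), monotone non-increasing by
    construction.  Fully deterministic given ``cfg.seed``.
    """
    if len(np.unique(data.y)) < 2:
        raise ValueError("feature selection requires two classes")
    rng = np.random.default_rng(cfg.seed)
    fit = _HoldoutFitness(data, cfg, rng)
    swarm = init_swarm(data.n_features, cfg, rng, fit=fit)

    best = min(swarm, key=lambda p: p.pbest_fitness)
    gbest_pos, gbest_fit = best.pbest_position.copy(), best.pbest_fitness
    history = [gbest_fit]

    for t in range(cfg.max_iter):
        w = cfg.inertia(t)
        fitnesses = np.empty(len(swarm))
        for i, p in enumerate(swarm):
            p.velocity = update_velocity(p, gbest_pos, cfg, rng, w=w)
            p.position = _repair_empty(update_position(p, rng), rng)
            fitnesses[i] = fit(p.position)
        gbest_pos, gbest_fit = update_pbest_gbest(swarm, fitnesses, gbest_pos, gbest_fit)
        history.append(gbest_fit)

    return SelectionResult(
        gbest_mask=gbest_pos.astype(np.int8),
        gbest_fitness=float(gbest_fit),
        fitness_history=np.asarray(history),
        config=cfg,
    )


def bpso_select_runs(
    data: FeatureDataset, cfg: BpsoConfig, n_runs: int, base_seed: int | None = None
) -> list[SelectionResult]:
    """Independent seeded BPSO runs (seeds base_seed .. base_seed + n_runs - 1).

    The mean best-so-far curve across runs is the usual way convergence is
    reported; compute it as ``np.mean([r.fitness_history for r in runs], 0)``.
    """
    base = cfg.seed if base_seed is None else base_seed
    return [bpso_select(data, replace(cfg, seed=base + i)) for i in range(n_runs)]
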