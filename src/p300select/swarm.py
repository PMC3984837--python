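"""Hybrid real-binary particle swarm optimization with an invisible wall.

Each particle is a 65-dimensional position x = [a, b1..b64]: one real
coordinate a in [-1, 1] encoding the FDA regularization through
lambda = 10**(5a) (an exponential decoding, so small steps in a sweep
lambda across ten orders of magnitude), and one binary coordinate per EEG
channel marking its inclusion.

Velocities follow the canonical update

    v <- w * v + c1 * eta1 * (pbest - x) + c2 * eta2 * (gbest - x)

with eta1, eta2 drawn uniformly in [0, 1] per component, then clamped to
+-V_max per component (0.1 real, 6 binary). The inertia w ramps linearly
from 0.9 to 0.4 over the run for the real coordinate and stays 1 for the
binary coordinates. The real position moves additively (x <- x + v); each
binary coordinate is resampled to 1 with probability S(v) = 1/(1+e^-v).

Boundary handling is an "invisible wall": positions with a outside [-1, 1]
or with an empty channel set are simply not evaluated and can never update
personal or global bests, but their velocities and positions keep updating
so they can drift back into the feasible region. The real coordinate is
never clipped.

gbest/pbest update on strict improvement only, so ties keep the earlier
position and runs are exactly reproducible from the seed. Evaluated
fitnesses are cached by position, since the CV fitness is deterministic
within a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SwarmConfig",
    "Particle",
    "IterationRecord",
    "SearchResult",
    "decode",
    "sigmoid",
    "inertia",
    "is_feasible",
    "update_velocity",
    "update_position",
    "run_search",
    "search_channels",
]


@dataclass(frozen=True)
class SwarmConfig:
    """PSO hyperparameters (defaults follow the study configuration)."""

    n_particles: int = 30
    max_iter: int = 100
    c1: float = 2.0
    c2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    inertia_binary: float = 1.0
    x_real_min: float = -1.0
    x_real_max: float = 1.0
    v_max_real: float = 0.1
    v_max_binary: float = 6.0
    target_fitness: float = 1.0
    n_bits: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1, c2 must be positive")
        if self.v_max_real <= 0 or self.v_max_binary <= 0:
            raise ValueError("velocity limits must be positive")
        if self.n_bits < 1:
            raise ValueError("need at least one binary coordinate")

    @property
    def n_dims(self) -> int:
        return 1 + self.n_bits

    def v_max(self) -> np.ndarray:
        v = np.full(self.n_dims, self.v_max_binary)
        v[0] = self.v_max_real
        return v


@dataclass
class Particle:
    position: np.ndarray  # [a, b1..bN]; bits stored as 0.0/1.0
    velocity: np.ndarray
    pbest_position: np.ndarray | None = None
    pbest_fitness: float | None = None


@dataclass
class IterationRecord:
    """Snapshot of the whole swarm at one iteration (before moving)."""

    iteration: int
    positions: np.ndarray  # (n_particles, n_dims)
    fitness: np.ndarray  # nan where infeasible
    feasible: np.ndarray  # bool
    payloads: list  # per-particle fitness detail (e.g. FitnessResult) or None


@dataclass
class SearchResult:
    gbest_position: np.ndarray | None
    gbest_fitness: float
    decoded: tuple[float, tuple[int, ...]] | None
    history: list[IterationRecord]
    iterations_run: int
    terminated_by: str  # "target" | "max_iter"
    gbest_payload: object = None

    @property
    def succeeded(self) -> bool:
        return self.gbest_position is not None

    def visited_points(self) -> list[tuple[int, float]]:
        """(n_channels, gm_accuracy) of every feasible evaluated position.

        Requires the fitness payloads to carry ``n_channels`` and ``gm``
        attributes (as :class:`~p300select.fitness.FitnessResult` does).
        """
        pts = []
        for rec in self.history:
            for ok, payload in zip(rec.feasible, rec.payloads):
                if ok and payload is not None:
                    pts.append((payload.n_channels, payload.gm))
        return pts

    def history_dataframe(self) -> pd.DataFrame:
        """Long-format evaluation log: one row per particle per iteration."""
        rows = []
        n_bits = self.history[0].positions.shape[1] - 1 if self.history else 0
        for rec in self.history:
            for i in range(rec.positions.shape[0]):
                row = {
                    "iteration": rec.iteration,
                    "particle": i,
                    "a": rec.positions[i, 0],
                    "bits": "".join(
                        str(int(b)) for b in rec.positions[i, 1:]
                    ),
                    "n_channels": int(rec.positions[i, 1:].sum()),
                    "feasible": bool(rec.feasible[i]),
                    "fitness": rec.fitness[i],
                }
                payload = rec.payloads[i]
                if payload is not None and hasattr(payload, "as_record"):
                    row.update(payload.as_record())
                rows.append(row)
        df = pd.DataFrame(rows)
        if not df.empty:
            df["n_bits"] = n_bits
        return df


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic transfer S(x) = 1/(1+e^-x) mapping velocity to bit probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def decode(position: np.ndarray, n_channels_total: int | None = None):
    """Decode a particle into (lambda, ascending channel index tuple).

    lambda = 10**(5a); channels are the indices of the set bits (0-based).
    An empty channel set decodes to an empty tuple (infeasible upstream).
    """
    position = np.asarray(position, dtype=np.float64)
    if n_channels_total is None:
        n_channels_total = position.shape[0] - 1
    if position.shape[0] != n_channels_total + 1:
        raise ValueError("position length must be 1 + n_channels_total")
    lam = 10.0 ** (5.0 * position[0])
    channels = tuple(int(j) for j in np.flatnonzero(position[1:] > 0.5))
    return lam, channels


def inertia(t: int, cfg: SwarmConfig) -> float:
    """Linearly decaying inertia for the real coordinate (0.9 -> 0.4)."""
    if t < 0 or t > cfg.max_iter:
        raise ValueError(f"iteration {t} outside [0, {cfg.max_iter}]")
    frac = t / cfg.max_iter
    return cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * frac


def is_feasible(position: np.ndarray, cfg: SwarmConfig | None = None) -> bool:
    """Inside the wall: a within [-1, 1] and at least one channel selected."""
    position = np.asarray(position, dtype=np.float64)
    lo = cfg.x_real_min if cfg is not None else -1.0
    hi = cfg.x_real_max if cfg is not None else 1.0
    return bool(lo <= position[0] <= hi and np.any(position[1:] > 0.5))


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    t: int,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """New clamped velocity from inertia, cognitive and social pulls.

    The inertia weight is ``inertia(t, cfg)`` for the real component and
    the constant binary inertia for bit components; eta1/eta2 are drawn
    independently per component. The summed velocity is clamped to
    +-V_max componentwise.
    """
    pbest = (
        particle.pbest_position
        if particle.pbest_position is not None
        else particle.position  # never evaluated: no cognitive pull yet
    )
    w = np.full(cfg.n_dims, cfg.inertia_binary)
    w[0] = inertia(t, cfg)
    eta1 = rng.uniform(size=cfg.n_dims)
    eta2 = rng.uniform(size=cfg.n_dims)
    v = (
        w * particle.velocity
        + cfg.c1 * eta1 * (pbest - particle.position)
        + cfg.c2 * eta2 * (gbest - particle.position)
    )
    vmax = cfg.v_max()
    return np.clip(v, -vmax, vmax)


def update_position(
    particle: Particle, cfg: SwarmConfig, rng: np.random.Generator
) -> np.ndarray:
    """Move: real coordinate additively, bits by sigmoid resampling.

    The real coordinate may leave [-1, 1]; the invisible wall handles it.
    Each bit becomes 1 with probability S(v_j), using a fresh uniform draw
    per bit.
    """
    x = particle.position.copy()
    x[0] += particle.velocity[0]
    r = rng.uniform(size=cfg.n_bits)
    x[1:] = (r < sigmoid(particle.velocity[1:])).astype(np.float64)
    return x


def _cache_key(position: np.ndarray) -> tuple:
    return (round(float(position[0]), 12),
            np.asarray(position[1:], dtype=np.uint8).tobytes())


def run_search(
    cfg: SwarmConfig,
    fitness_fn: Callable[[float, tuple[int, ...]], object],
    rng: np.random.Generator | None = None,
) -> SearchResult:
    """Run the PSO loop against a fitness function of (lambda, channels).

    ``fitness_fn`` receives the decoded particle and returns either a float
    or an object with a scalar ``fitness`` attribute (kept as the history
    payload). Initialization: a ~ U[-1, 1], bits Bernoulli(0.5),
    velocities zero. Each iteration evaluates all feasible particles
    (cached by position), updates pbest/gbest on strict improvement,
    records the full swarm snapshot, stops if gbest reached the target
    fitness, and otherwise moves the swarm. Fully determined by cfg.seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    particles = []
    for _ in range(cfg.n_particles):
        x = np.empty(cfg.n_dims)
        x[0] = rng.uniform(cfg.x_real_min, cfg.x_real_max)
        x[1:] = (rng.uniform(size=cfg.n_bits) < 0.5).astype(np.float64)
        particles.append(Particle(position=x, velocity=np.zeros(cfg.n_dims)))

    gbest_position: np.ndarray | None = None
    gbest_fitness = -np.inf
    gbest_payload = None
    cache: dict[tuple, tuple[float, object]] = {}
    history: list[IterationRecord] = []
    terminated_by = "max_iter"
    iterations_run = 0

    for t in range(1, cfg.max_iter + 1):
        positions = np.stack([p.position for p in particles])
        feasible = np.array([is_feasible(p.position, cfg) for p in particles])
        fit_vals = np.full(cfg.n_particles, np.nan)
        payloads: list = [None] * cfg.n_particles

        for i, p in enumerate(particles):
            if not feasible[i]:
                continue
            key = _cache_key(p.position)
            if key in cache:
                f, payload = cache[key]
            else:
                lam, channels = decode(p.position, cfg.n_bits)
                result = fitness_fn(lam, channels)
                if hasattr(result, "fitness"):
                    payload, f = result, float(result.fitness)
                else:
                    payload, f = None, float(result)
                cache[key] = (f, payload)
            fit_vals[i] = f
            payloads[i] = payload
            if p.pbest_fitness is None or f > p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
            if f > gbest_fitness:
                gbest_fitness = f
                gbest_position = p.position.copy()
                gbest_payload = payload

        history.append(IterationRecord(
            iteration=t, positions=positions, fitness=fit_vals,
            feasible=feasible, payloads=payloads,
        ))
        iterations_run = t

        if gbest_position is not None and gbest_fitness >= cfg.target_fitness:
            terminated_by = "target"
            break

        # movement; infeasible particles move too (only evaluation and
        # best-updates are skipped by the invisible wall)
        for p in particles:
            g = gbest_position if gbest_position is not None else (
                p.pbest_position if p.pbest_position is not None else p.position
            )
            p.velocity = update_velocity(p, g, t - 1, cfg, rng)
            p.position = update_position(p, cfg, rng)

    if gbest_position is None:
        return SearchResult(
            gbest_position=None, gbest_fitness=float("nan"), decoded=None,
            history=history, iterations_run=iterations_run,
            terminated_by=terminated_by,
        )
    return SearchResult(
        gbest_position=gbest_position,
        gbest_fitness=float(gbest_fitness),
        decoded=decode(gbest_position, cfg.n_bits),
        history=history,
        iterations_run=iterations_run,
        terminated_by=terminated_by,
        gbest_payload=gbest_payload,
    )


def search_channels(
    dataset,
    preproc,
    cfg: SwarmConfig,
    weights=None,
    fold_seed: int = 0,
    n_folds: int = 10,
) -> SearchResult:
    """End-to-end search on an epoch dataset.

    Preprocesses the dataset (band-pass + baseline), builds the CV fitness
    evaluator with a frozen fold assignment, and runs the swarm. The
    dataset should be the *training* half only. ``cfg.n_bits`` must equal
    the montage size.
    """
    from .fitness import CVFitnessEvaluator, FitnessWeights
    from .preprocessing import feature_tensor, preprocess_dataset

    if weights is None:
        weights = FitnessWeights(0.5, 0.5)
    if cfg.n_bits != dataset.n_channels:
        raise ValueError(
            f"cfg.n_bits = {cfg.n_bits} must equal the montage size "
            f"{dataset.n_channels}"
        )
    clean = preprocess_dataset(dataset, preproc)
    features = feature_tensor(clean, preproc)
    evaluator = CVFitnessEvaluator(
        features, clean.labels, weights=weights,
        n_folds=n_folds, fold_seed=fold_seed,
    )
    return run_search(cfg, evaluator.particle_fitness)
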