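"""High-throughput, low-iteration batch optimizers.

Three algorithms share one loop: sample a Sobol cloud of designs around the
current center, evaluate each design's fitness on the landscape, select the
top-performing fraction F as parents, and move the center:

* ``hill_climb``  — next center is the geometric (arithmetic) center of the
  parents.
* ``projection``  — the hill-climb move is projected twofold along the
  vector from the previous center through the parent center, trading
  overshoot risk for speed.
* ``cma_es``      — a simplified covariance-matrix-adaptation strategy: the
  next center is the fitness-weighted average of the parents, and the shape
  of the sampling cloud adapts to the parents' spread and to the direction
  of the most recent move.

Iteration counts are deliberately small (default 5): each iteration models
one design-build-test cycle, the expensive unit of a genetic engineering
campaign, while the per-iteration library size n is cheap to scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape
from .sampling import SobolEngine, sample_cloud

__all__ = [
    "ALGORITHMS",
    "OptimizerConfig",
    "IterationRecord",
    "OptimizationTrace",
    "select_parents",
    "hill_climb_center",
    "projection_center",
    "cma_update",
    "run_optimization",
    "trace_to_table",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("hill_climb", "projection", "cma_es")

# shape-update mixing constants for the CMA variant: cmu weights the parents'
# empirical covariance, c1 the rank-one directional term
CMA_C_MU = 0.5
CMA_C_1 = 0.2
_SHAPE_EIG_FLOOR = 1e-10


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters: L, SC, sigma, n, I, F, algorithm, seed."""

    landscape_name: str
    start_coordinates: tuple[float, ...]
    sobol_radius: float
    samples_per_iteration: int
    parent_fraction: float
    algorithm: str
    seed: int
    iterations: int = 5

    def __post_init__(self):
        object.__setattr__(
            self, "start_coordinates", tuple(float(c) for c in self.start_coordinates)
        )
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if not (0 < self.parent_fraction <= 1):
            raise ValueError(f"parent_fraction must be in (0, 1], got {self.parent_fraction}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.samples_per_iteration < 1:
            raise ValueError(
                f"samples_per_iteration must be >= 1, got {self.samples_per_iteration}"
            )
        if self.sobol_radius < 0:
            raise ValueError(f"sobol_radius must be >= 0, got {self.sobol_radius}")


@dataclass(frozen=True)
class IterationRecord:
    index: int
    center: np.ndarray
    center_fitness: float
    samples: np.ndarray
    sample_fitnesses: np.ndarray
    parent_indices: np.ndarray


@dataclass(frozen=True)
class OptimizationTrace:
    config: OptimizerConfig
    iterations: tuple[IterationRecord, ...]
    performance: float


def parent_count(n: int, parent_fraction: float) -> int:
    """Top-performer count: max(1, round(F * n)) with half-up rounding."""
    return max(1, int(math.floor(parent_fraction * n + 0.5)))


def select_parents(fitnesses, parent_fraction: float) -> np.ndarray:
    """Indices of the top max(1, round(F*n)) fitnesses.

    Ties at the cutoff are broken by lower sample index; the result is
    ordered by decreasing fitness (ascending index within ties).
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("cannot select parents from an empty fitness list")
    if not (0 < parent_fraction <= 1):
        raise ValueError(f"parent_fraction must be in (0, 1], got {parent_fraction}")
    k = parent_count(len(f), parent_fraction)
    order = np.argsort(-f, kind="stable")
    return order[:k]


def hill_climb_center(parents) -> np.ndarray:
    """Geometric center (componentwise arithmetic mean) of the parents."""
    p = np.asarray(parents, dtype=float)
    if p.ndim != 2 or len(p) < 1:
        raise ValueError("need at least one parent point")
    return p.mean(axis=0)


def projection_center(previous_center, parents) -> np.ndarray:
    """Project twofold along the vector from the previous center to the
    parent center: next = prev + 2 * (mean(parents) - prev)."""
    prev = np.asarray(previous_center, dtype=float)
    mean = hill_climb_center(parents)
    return prev + 2.0 * (mean - prev)


def cma_update(
    previous_center,
    parents,
    parent_fitnesses,
    previous_shape,
    radius: float = 1.0,
    c_mu: float = CMA_C_MU,
    c_1: float = CMA_C_1,
    weight_mode: str = "proportional",
):
    """One covariance-adaptation step.

    The next center is the weighted average of the parents.  Default
    weights are fitness-proportional after shifting by the minimum parent
    fitness (so the worst parent gets weight 0 and no weight is negative);
    ``weight_mode='rank'`` uses the canonical log-rank weights instead.

    The sampling-shape matrix is updated as a convex-ish mixture of the
    previous shape, the weighted empirical covariance of the parents about
    the new center (in radius-normalized coordinates), and a rank-one term
    along the unit direction of the center move that biases subsequent
    sampling toward the direction of progress.  The result is symmetrized
    and, if necessary, ridge-regularized back to positive definiteness.
    Returns ``(next_center, next_shape)``.
    """
    prev = np.asarray(previous_center, dtype=float)
    p = np.asarray(parents, dtype=float)
    f = np.asarray(parent_fitnesses, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("cma_update needs at least 2 parents")
    if len(f) != len(p):
        raise ValueError("one fitness per parent required")
    shape = np.asarray(previous_shape, dtype=float)

    if weight_mode == "proportional":
        w = f - f.min()
    elif weight_mode == "rank":
        mu = len(f)
        ranks = np.empty(mu, dtype=float)
        ranks[np.argsort(-f, kind="stable")] = np.arange(1, mu + 1)
        w = np.maximum(np.log(mu + 0.5) - np.log(ranks), 0.0)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    total = w.sum()
    if total <= 0:  # all parents equally fit -> uniform weights
        w = np.full(len(f), 1.0 / len(f))
    else:
        w = w / total

    center = w @ p

    scale = radius if radius > 0 else 1.0
    dev = (p - center[None, :]) / scale
    cov = (dev * w[:, None]).T @ dev

    shift = (center - prev) / scale
    norm = np.linalg.norm(shift)
    if norm > 0:
        u = shift / norm
        rank_one = np.outer(u, u)
    else:
        rank_one = np.zeros_like(shape)

    new_shape = (1.0 - c_1 - c_mu) * shape + c_mu * cov + c_1 * rank_one
    new_shape = 0.5 * (new_shape + new_shape.T)
    eigvals = np.linalg.eigvalsh(new_shape)
    if eigvals[0] < _SHAPE_EIG_FLOOR:
        if np.allclose(dev, 0):
            logger.warning(
                "all parents identical; sampling shape degenerated, ridge floor applied"
            )
        new_shape = new_shape + (_SHAPE_EIG_FLOOR - eigvals[0] + 1e-12) * np.eye(len(shape))
    return center, new_shape


def run_optimization(config: OptimizerConfig, landscape: Landscape) -> OptimizationTrace:
    """Run one seeded optimization and record every iteration.

    Iteration 1 samples around the start coordinates; each subsequent
    iteration samples around the center produced by the algorithm's update
    rule.  The trace is fully reproducible from (config, seed).
    """
    dims = landscape.dimensions
    sc = np.asarray(config.start_coordinates, dtype=float)
    if sc.shape != (dims,):
        raise ValueError(
            f"start_coordinates have {sc.shape[0] if sc.ndim else 0} dimensions, "
            f"landscape has {dims}"
        )
    lo = np.array([b[0] for b in landscape.bounds])
    hi = np.array([b[1] for b in landscape.bounds])
    if np.any(sc < lo) or np.any(sc > hi):
        raise ValueError("start_coordinates must lie within the landscape bounds")

    engine = SobolEngine(dims, config.seed)
    center = sc
    shape = np.eye(dims) if config.algorithm == "cma_es" else None
    records: list[IterationRecord] = []
    for it in range(1, config.iterations + 1):
        center_fitness = landscape.evaluate(center)
        cloud = sample_cloud(
            engine,
            center,
            config.sobol_radius,
            config.samples_per_iteration,
            landscape.bounds,
            shape=shape,
        )
        fits = landscape.evaluate_batch(cloud.points)
        parent_idx = select_parents(fits, config.parent_fraction)
        records.append(
            IterationRecord(
                index=it,
                center=center.copy(),
                center_fitness=center_fitness,
                samples=cloud.points,
                sample_fitnesses=fits,
                parent_indices=parent_idx,
            )
        )
        parents = cloud.points[parent_idx]
        if config.algorithm == "hill_climb":
            center = hill_climb_center(parents)
        elif config.algorithm == "projection":
            center = projection_center(center, parents)
        else:
            if len(parents) >= 2:
                center, shape = cma_update(
                    center,
                    parents,
                    fits[parent_idx],
                    shape,
                    radius=config.sobol_radius,
                )
            else:
                center = parents[0].copy()
    perf = float(np.sum([r.center_fitness for r in records]))
    return OptimizationTrace(config=config, iterations=tuple(records), performance=perf)


def trace_to_table(trace: OptimizationTrace, run_id: str = "run") -> pd.DataFrame:
    """Long-format trace export: one row per center/sample with its role."""
    dims = len(trace.config.start_coordinates)
    coord_cols = [f"x{d + 1}" for d in range(dims)]
    rows = []
    for rec in trace.iterations:
        rows.append(
            [run_id, rec.index, "center", *rec.center, rec.center_fitness]
        )
        parent_set = set(int(i) for i in rec.parent_indices)
        for i, (pt, fv) in enumerate(zip(rec.samples, rec.sample_fitnesses)):
            role = "parent" if i in parent_set else "sample"
            rows.append([run_id, rec.index, role, *pt, fv])
    return pd.DataFrame(rows, columns=["run_id", "iteration", "role", *coord_cols, "fitness"])
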