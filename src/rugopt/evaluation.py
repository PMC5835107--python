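"""Run scoring and (sigma, F) parameter sweeps.

An optimization run is scored by the area under its center-point fitness
trajectory over the first I iterations (rectangle rule by default), so the
score rewards both the fitness level reached and how quickly it was
reached.  Reliability is the sample standard deviation of that score over
replicate runs.  A parameter sweep evaluates one algorithm on one landscape
over a full factorial (sigma, F) lattice with seeded replicates per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Landscape
from .optimizers import OptimizationTrace, OptimizerConfig, run_optimization

__all__ = [
    "DEFAULT_SIGMA_LATTICE",
    "DEFAULT_F_LATTICE",
    "PerformanceScore",
    "SweepCell",
    "SweepResult",
    "performance",
    "reliability",
    "derive_seed",
    "parameter_sweep",
]

# coarse default lattice spanning the sampling spreads and parent fractions
# worth exploring on a [0, 1000]^2 domain
DEFAULT_SIGMA_LATTICE = (50.0, 100.0, 200.0, 400.0)
DEFAULT_F_LATTICE = (0.1, 0.2, 0.4, 0.8)


@dataclass(frozen=True)
class PerformanceScore:
    value: float
    iterations_used: int


@dataclass(frozen=True)
class SweepCell:
    sobol_radius: float
    parent_fraction: float
    replicate_performances: tuple[float, ...]
    mean_performance: float
    reliability: float


@dataclass(frozen=True)
class SweepResult:
    algorithm: str
    landscape_name: str
    sigma_values: tuple[float, ...]
    f_values: tuple[float, ...]
    cells: tuple[SweepCell, ...]
    start_coordinates: tuple[float, ...]
    samples_per_iteration: int
    iterations: int
    replicates: int
    base_seed: int

    def cell(self, sigma: float, f: float) -> SweepCell:
        for c in self.cells:
            if c.sobol_radius == sigma and c.parent_fraction == f:
                return c
        raise KeyError(f"no cell at sigma={sigma}, F={f}")

    def to_frame(self) -> pd.DataFrame:
        """Heatmap-ready per-cell table."""
        return pd.DataFrame(
            {
                "algorithm": self.algorithm,
                "landscape": self.landscape_name,
                "sigma": [c.sobol_radius for c in self.cells],
                "F": [c.parent_fraction for c in self.cells],
                "mean_performance": [c.mean_performance for c in self.cells],
                "reliability": [c.reliability for c in self.cells],
                "n_replicates": self.replicates,
            }
        )

    def replicates_frame(self) -> pd.DataFrame:
        """Per-replicate long table."""
        rows = []
        for c in self.cells:
            for r, perf in enumerate(c.replicate_performances):
                rows.append(
                    [self.algorithm, self.landscape_name, c.sobol_radius,
                     c.parent_fraction, r, perf]
                )
        return pd.DataFrame(
            rows, columns=["algorithm", "landscape", "sigma", "F", "replicate", "performance"]
        )

    def best_cell(self) -> SweepCell:
        return max(self.cells, key=lambda c: c.mean_performance)


def performance(trace: OptimizationTrace, rule: str = "rectangle") -> PerformanceScore:
    """Area under the center-point fitness trajectory.

    ``rectangle`` (default) sums the center fitnesses with unit iteration
    spacing; ``trapezoid`` differs only in halving the endpoint weights.
    """
    if not trace.iterations:
        raise ValueError("trace has no iterations")
    f = np.array([rec.center_fitness for rec in trace.iterations])
    if rule == "rectangle":
        value = float(f.sum())
    elif rule == "trapezoid":
        value = float(np.trapezoid(f)) if len(f) > 1 else float(f[0])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return PerformanceScore(value=value, iterations_used=len(f))


def reliability(performances) -> float:
    """Sample standard deviation (n-1 denominator) of replicate scores."""
    vals = np.asarray(performances, dtype=float)
    if vals.size < 2:
        raise ValueError("reliability needs at least 2 replicate performances")
    return float(np.std(vals, ddof=1))


def derive_seed(base_seed: int, *indices: int) -> int:
    """Order-independent per-cell/replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] % (2**31))


def parameter_sweep(
    algorithm: str,
    landscape: Landscape,
    sigma_values=DEFAULT_SIGMA_LATTICE,
    f_values=DEFAULT_F_LATTICE,
    start_coordinates=(300.0, 700.0),
    samples_per_iteration: int = 50,
    iterations: int = 5,
    replicates: int = 5,
    base_seed: int = 0,
) -> SweepResult:
    """Full factorial (sigma, F) sweep with seeded replicates per cell.

    Every (cell, replicate) run draws its seed independently from
    ``base_seed`` and the cell/replicate indices, so results do not depend
    on execution order and the whole sweep is reproducible.
    """
    sigmas = tuple(float(s) for s in sigma_values)
    fs = tuple(float(f) for f in f_values)
    if not sigmas or not fs:
        raise ValueError("sigma_values and f_values must be nonempty")
    if replicates < 2:
        raise ValueError("replicates must be >= 2 (reliability is undefined otherwise)")
    cells = []
    for i_s, sigma in enumerate(sigmas):
        for i_f, f in enumerate(fs):
            perfs = []
            for r in range(replicates):
                cfg = OptimizerConfig(
                    landscape_name=landscape.name,
                    start_coordinates=start_coordinates,
                    sobol_radius=sigma,
                    samples_per_iteration=samples_per_iteration,
                    parent_fraction=f,
                    algorithm=algorithm,
                    seed=derive_seed(base_seed, i_s, i_f, r),
                    iterations=iterations,
                )
                trace = run_optimization(cfg, landscape)
                perfs.append(performance(trace).value)
            cells.append(
                SweepCell(
                    sobol_radius=sigma,
                    parent_fraction=f,
                    replicate_performances=tuple(perfs),
                    mean_performance=float(np.mean(perfs)),
                    reliability=reliability(perfs),
                )
            )
    return SweepResult(
        algorithm=algorithm,
        landscape_name=landscape.name,
        sigma_values=sigmas,
        f_values=fs,
        cells=tuple(cells),
        start_coordinates=tuple(float(c) for c in start_coordinates),
        samples_per_iteration=samples_per_iteration,
        iterations=iterations,
        replicates=replicates,
        base_seed=base_seed,
    )
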