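"""Seeded quasi-random design sampling.

Candidate designs are drawn from a scrambled Sobol sequence, mapped through
the inverse standard-normal transform so the cloud of sampled expression
levels follows a normal distribution around the current center point, scaled
by the spread parameter sigma (and, for the covariance-adapting optimizer,
by a shape matrix), and clipped componentwise to the domain bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import qmc

__all__ = ["SobolEngine", "SampleCloud", "sobol_unit", "sample_cloud"]

# unit-cube values are nudged away from {0, 1} before the inverse-normal
# transform, which maps the endpoints to +/- infinity
_UNIT_EPS = 2.0**-53


class SobolEngine:
    """A seeded, scrambled Sobol stream.

    Successive draws continue the sequence; the same (dimensions, seed)
    pair always reproduces the same stream.
    """

    def __init__(self, dimensions: int, seed: int):
        if dimensions < 1:
            raise ValueError(f"dimensions must be >= 1, got {dimensions}")
        self.dimensions = dimensions
        self.seed = seed
        self.counter = 0
        self._sobol = qmc.Sobol(d=dimensions, scramble=True, seed=seed)

    def random(self, n: int) -> np.ndarray:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        with warnings.catch_warnings():
            # library sizes are experimental budgets, rarely powers of two;
            # the balance warning is expected and not actionable here
            warnings.filterwarnings(
                "ignore", message="The balance properties of Sobol"
            )
            pts = self._sobol.random(n)
        self.counter += n
        return pts


@dataclass(frozen=True)
class SampleCloud:
    """One iteration's batch of candidate designs around a center point."""

    center: np.ndarray
    radius: float
    points: np.ndarray
    shape: np.ndarray | None = None


def sobol_unit(engine: SobolEngine, n: int) -> np.ndarray:
    """Draw the next ``n`` points of the engine's stream in [0, 1)^d."""
    return engine.random(n)


def _shape_factor(shape: np.ndarray, dimensions: int) -> np.ndarray:
    m = np.asarray(shape, dtype=float)
    if m.shape != (dimensions, dimensions):
        raise ValueError(f"shape matrix must be {dimensions}x{dimensions}, got {m.shape}")
    if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12):
        raise ValueError("shape matrix must be symmetric")
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError("shape matrix must be positive-definite") from exc


def sample_cloud(
    engine: SobolEngine,
    center,
    radius: float,
    n: int,
    bounds,
    shape=None,
) -> SampleCloud:
    """Sample ``n`` designs around ``center``.

    Unit-cube Sobol points are transformed to a standard normal per
    coordinate, scaled by ``radius`` (the per-dimension standard deviation,
    in expression units) and by the Cholesky factor of ``shape`` when one
    is given, translated to ``center``, then clipped to ``bounds``.
    """
    c = np.asarray(center, dtype=float)
    if c.shape != (engine.dimensions,):
        raise ValueError(f"center has shape {c.shape}, expected ({engine.dimensions},)")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    u = sobol_unit(engine, n)
    z = ndtri(np.clip(u, _UNIT_EPS, 1.0 - _UNIT_EPS))
    if shape is not None:
        z = z @ _shape_factor(shape, engine.dimensions).T
    pts = c[None, :] + radius * z
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    np.clip(pts, lo[None, :], hi[None, :], out=pts)
    return SampleCloud(
        center=c,
        radius=float(radius),
        points=pts,
        shape=None if shape is None else np.asarray(shape, dtype=float),
    )
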