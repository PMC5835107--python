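"""Sum-of-Gaussians expression landscapes.

A landscape maps a point in multi-gene expression space (one axis per gene,
in arbitrary "expression units") to a scalar system performance, e.g. the
titer of a target metabolite.  Landscapes are built by summing axis-aligned
Gaussian sub-peaks; varying the per-axis spread of the sub-peaks while
keeping their locations and heights fixed produces families of landscapes
that differ only in ruggedness.
"""

from __future__ import annotations

import ast
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GaussianPeak",
    "LandscapeSpec",
    "Landscape",
    "LandscapeFormatError",
    "load_landscape",
    "save_landscape",
    "grid_sample",
    "grid_to_table",
    "builtin_model_landscapes",
    "builtin_landscape",
    "global_maximum",
    "import_supplementary_surface",
]

SPEC_FORMAT_VERSION = 1


class LandscapeFormatError(ValueError):
    """A landscape spec file is malformed or violates an invariant."""


@dataclass(frozen=True)
class GaussianPeak:
    """One axis-aligned Gaussian sub-peak.

    Parameters
    ----------
    center : per-dimension location of the peak, in expression units.
    amplitude : fitness contribution at the center; must be nonnegative.
    spread : per-dimension standard deviation of the Gaussian; all > 0.
    """

    center: tuple[float, ...]
    amplitude: float
    spread: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "spread", tuple(float(s) for s in self.spread))
        object.__setattr__(self, "amplitude", float(self.amplitude))
        if not math.isfinite(self.amplitude) or self.amplitude < 0:
            raise LandscapeFormatError(
                f"peak amplitude must be finite and >= 0, got {self.amplitude!r}"
            )
        if len(self.center) != len(self.spread):
            raise LandscapeFormatError(
                f"peak center has {len(self.center)} dimensions but spread has "
                f"{len(self.spread)}"
            )
        for s in self.spread:
            if not math.isfinite(s) or s <= 0:
                raise LandscapeFormatError(
                    f"peak spread components must be finite and > 0, got {s!r}"
                )
        for c in self.center:
            if not math.isfinite(c):
                raise LandscapeFormatError(f"peak center component not finite: {c!r}")


@dataclass(frozen=True)
class LandscapeSpec:
    """Declarative description of a landscape: domain plus peak table."""

    name: str
    dimensions: int
    bounds: tuple[tuple[float, float], ...]
    peaks: tuple[GaussianPeak, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "bounds", tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        )
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.dimensions < 1:
            raise LandscapeFormatError(f"dimensions must be >= 1, got {self.dimensions}")
        if len(self.bounds) != self.dimensions:
            raise LandscapeFormatError(
                f"expected {self.dimensions} bound intervals, got {len(self.bounds)}"
            )
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
                raise LandscapeFormatError(f"empty or non-finite bound interval ({lo}, {hi})")
        if not self.peaks:
            raise LandscapeFormatError("a landscape needs at least one peak")
        for i, pk in enumerate(self.peaks):
            if len(pk.center) != self.dimensions:
                raise LandscapeFormatError(
                    f"peak {i} has {len(pk.center)} dimensions, landscape has "
                    f"{self.dimensions}"
                )
            for d, (c, (lo, hi)) in enumerate(zip(pk.center, self.bounds)):
                if not (lo <= c <= hi):
                    raise LandscapeFormatError(
                        f"peak {i} center component {d} ({c}) outside bounds [{lo}, {hi}]"
                    )


class Landscape:
    """Evaluatable sum-of-Gaussians fitness surface.

    fitness(p) = sum_j A_j * exp(-sum_d (p_d - c_jd)^2 / (2 s_jd^2))

    The formula is defined on all of R^d; domain bounds constrain samplers,
    not evaluation.
    """

    def __init__(self, spec: LandscapeSpec):
        self.spec = spec
        self._centers = np.array([p.center for p in spec.peaks], dtype=float)
        self._amplitudes = np.array([p.amplitude for p in spec.peaks], dtype=float)
        self._spreads = np.array([p.spread for p in spec.peaks], dtype=float)
        self._inv_two_s2 = 1.0 / (2.0 * self._spreads**2)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def dimensions(self) -> int:
        return self.spec.dimensions

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return self.spec.bounds

    def _eval(self, points: np.ndarray) -> np.ndarray:
        # (n, d) -> (n,); single-point evaluate routes through the same
        # kernel so batch and scalar paths are bitwise identical.
        arg = ((points[:, None, :] - self._centers[None, :, :]) ** 2
               * self._inv_two_s2[None, :, :]).sum(axis=2)
        return (self._amplitudes[None, :] * np.exp(-arg)).sum(axis=1)

    def evaluate(self, point: Sequence[float]) -> float:
        p = np.asarray(point, dtype=float)
        if p.shape != (self.dimensions,):
            raise ValueError(
                f"point has shape {p.shape}, expected ({self.dimensions},)"
            )
        return float(self._eval(p[None, :])[0])

    def evaluate_batch(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if pts.size == 0:
            return np.empty(0, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.dimensions:
            raise ValueError(
                f"points have shape {pts.shape}, expected (n, {self.dimensions})"
            )
        return self._eval(pts)

    def __repr__(self):
        return (f"Landscape(name={self.name!r}, dimensions={self.dimensions}, "
                f"peaks={len(self.spec.peaks)})")


# ---------------------------------------------------------------------------
# spec-file I/O (JSON, versioned "format": 1)

def _spec_to_dict(spec: LandscapeSpec) -> dict:
    return {
        "format": SPEC_FORMAT_VERSION,
        "name": spec.name,
        "dimensions": spec.dimensions,
        "bounds": [[lo, hi] for lo, hi in spec.bounds],
        "peaks": [
            {"center": list(p.center), "amplitude": p.amplitude, "spread": list(p.spread)}
            for p in spec.peaks
        ],
    }


def save_landscape(landscape: Landscape, path) -> None:
    """Write a landscape spec file (JSON).  Numeric fields round-trip exactly."""
    Path(path).write_text(json.dumps(_spec_to_dict(landscape.spec), indent=2) + "\n")


def load_landscape(path) -> Landscape:
    """Load a landscape from a versioned JSON spec file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"landscape spec file not found: {p}")
    try:
        raw = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise LandscapeFormatError(f"{p}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise LandscapeFormatError(f"{p}: top level must be an object")
    fmt = raw.get("format")
    if fmt != SPEC_FORMAT_VERSION:
        raise LandscapeFormatError(
            f"{p}: field 'format' must be {SPEC_FORMAT_VERSION}, got {fmt!r}"
        )
    for key in ("name", "dimensions", "bounds", "peaks"):
        if key not in raw:
            raise LandscapeFormatError(f"{p}: missing required field {key!r}")
    try:
        peaks = tuple(
            GaussianPeak(center=pk["center"], amplitude=pk["amplitude"], spread=pk["spread"])
            for pk in raw["peaks"]
        )
    except (KeyError, TypeError) as exc:
        raise LandscapeFormatError(f"{p}: malformed entry in field 'peaks' ({exc})") from exc
    spec = LandscapeSpec(
        name=str(raw["name"]),
        dimensions=int(raw["dimensions"]),
        bounds=tuple(tuple(b) for b in raw["bounds"]),
        peaks=peaks,
    )
    return Landscape(spec)


# ---------------------------------------------------------------------------
# grid sampling

def grid_sample(landscape: Landscape, points_per_axis: int):
    """Evaluate the landscape on a full Cartesian grid.

    Coordinates are evenly spaced per axis with both bound endpoints
    included (spacing = range / (points_per_axis - 1)).  Returns
    ``(points, fitnesses)`` with ``points_per_axis ** dimensions`` rows.
    """
    if points_per_axis < 2:
        raise ValueError(f"points_per_axis must be >= 2, got {points_per_axis}")
    axes = [np.linspace(lo, hi, points_per_axis) for lo, hi in landscape.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([m.ravel() for m in mesh])
    return points, landscape.evaluate_batch(points)


def grid_to_table(points: np.ndarray, fitnesses: np.ndarray) -> pd.DataFrame:
    """Grid export: one coordinate column per dimension plus 'fitness'."""
    cols = {f"x{d + 1}": points[:, d] for d in range(points.shape[1])}
    cols["fitness"] = fitnesses
    return pd.DataFrame(cols)


def global_maximum(landscape: Landscape, points_per_axis: int = 200):
    """Locate the global maximum: dense-grid argmax refined by local search.

    Returns ``(point, fitness)`` with the point clipped to bounds.
    """
    points, fits = grid_sample(landscape, points_per_axis)
    x0 = points[int(np.argmax(fits))]
    lo = np.array([b[0] for b in landscape.bounds])
    hi = np.array([b[1] for b in landscape.bounds])
    res = optimize.minimize(
        lambda p: -landscape.evaluate_batch(p[None, :])[0],
        x0,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
    )
    best = np.clip(res.x, lo, hi)
    val = landscape.evaluate_batch(best[None, :])[0]
    if val < fits.max():  # local refine should never lose to the grid
        best, val = x0, fits.max()
    return best, float(val)


# ---------------------------------------------------------------------------
# built-in model landscapes
#
# Three two-gene model landscapes over [0, 1000]^2 sharing one table of
# sub-peak locations and heights; only the per-axis spreads differ, scaled
# by a per-landscape factor.  The factors were calibrated once (bisection
# on the default ruggedness protocol: 200x200 grid, 100-unit bins to 700,
# N = 700) so the fitted NK coefficients land at k ~ 0.83 (smooth),
# 1.07 (medium) and 2.07 (rugged).

# (cx, cy), amplitude, (relative sx, relative sy)
_PEAK_TABLE = (
    ((500.0, 420.0), 1.00, (1.00, 1.05)),
    ((230.0, 760.0), 0.72, (0.95, 0.90)),
    ((760.0, 770.0), 0.68, (1.10, 0.95)),
    ((190.0, 300.0), 0.60, (0.90, 1.00)),
    ((810.0, 240.0), 0.66, (1.00, 0.85)),
    ((420.0, 810.0), 0.55, (0.85, 1.00)),
    ((660.0, 560.0), 0.62, (1.05, 1.10)),
    ((300.0, 540.0), 0.52, (0.95, 0.90)),
    ((620.0, 140.0), 0.58, (1.00, 1.00)),
    ((860.0, 540.0), 0.50, (0.90, 1.05)),
    ((140.0, 110.0), 0.45, (1.00, 0.95)),
    ((700.0, 870.0), 0.52, (0.95, 1.00)),
)

# per-landscape spread scale, in expression units (calibrated; see module note)
_SPREAD_SCALE = {
    "smooth": 150.7,
    "medium": 124.314,
    "rugged": 97.759,
}

_BUILTIN_BOUNDS = ((0.0, 1000.0), (0.0, 1000.0))


def builtin_landscape(name: str) -> Landscape:
    """Return one of the built-in model landscapes: smooth, medium or rugged."""
    if name not in _SPREAD_SCALE:
        raise KeyError(
            f"unknown builtin landscape {name!r}; choose from "
            f"{sorted(_SPREAD_SCALE)}"
        )
    scale = _SPREAD_SCALE[name]
    peaks = tuple(
        GaussianPeak(center=c, amplitude=a, spread=(rs[0] * scale, rs[1] * scale))
        for c, a, rs in _PEAK_TABLE
    )
    return Landscape(LandscapeSpec(name=name, dimensions=2, bounds=_BUILTIN_BOUNDS, peaks=peaks))


def builtin_model_landscapes() -> tuple[Landscape, Landscape, Landscape]:
    """The smooth / medium / rugged model trio (shared centers and heights)."""
    return tuple(builtin_landscape(n) for n in ("smooth", "medium", "rugged"))


# ---------------------------------------------------------------------------
# supplementary-surface import

def import_supplementary_surface(path) -> Landscape:
    """Load a landscape from a supplementary surface-definition script.

    Expected layout: a Python source file that assigns (to any variable) a
    literal list of rows, each row being the five numbers
    ``[amplitude, x_center, y_center, x_spread, y_spread]`` for one Gaussian
    sub-peak over the [0, 1000] x [0, 1000] domain.  The first such
    assignment found is used.  Only literals are read; the file is never
    executed.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"supplementary file required but not found: {p}. Provide the "
            "surface-definition script (e.g. surface_matrix-low.py) to load "
            "this landscape."
        )
    try:
        tree = ast.parse(p.read_text())
    except SyntaxError as exc:
        raise LandscapeFormatError(f"{p}: not parseable as Python ({exc})") from exc
    rows = None
    for node in ast.walk(tree):
        if not isinstance(node, (ast.Assign, ast.AnnAssign)):
            continue
        value = node.value
        if value is None:
            continue
        try:
            candidate = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            continue
        if (isinstance(candidate, (list, tuple)) and candidate
                and all(isinstance(r, (list, tuple)) and len(r) == 5 for r in candidate)):
            rows = candidate
            break
    if rows is None:
        raise LandscapeFormatError(
            f"{p}: no literal peak table found (expected a list of "
            "[amplitude, x_center, y_center, x_spread, y_spread] rows)"
        )
    peaks = tuple(
        GaussianPeak(center=(r[1], r[2]), amplitude=r[0], spread=(r[3], r[4]))
        for r in rows
    )
    spec = LandscapeSpec(
        name=p.stem, dimensions=2, bounds=_BUILTIN_BOUNDS, peaks=peaks
    )
    return Landscape(spec)
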