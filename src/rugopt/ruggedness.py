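"""Landscape-autocorrelation ruggedness quantification.

The ruggedness of a fitness landscape is estimated from sampled points in
three stages:

1. For every unordered pair of sampled points, record the Euclidean
   distance in expression space and the squared difference of the two
   fitness values; average the squared differences within fixed distance
   bins (default 0-100, 100-200, ..., 600-700 expression units).
2. Normalize by the variance of the whole landscape, approximated by the
   farthest bin's mean squared difference (pairs farther apart than the
   bin range are constrained by the finite domain and under-sampled):
   ``LA(d) = 1 - sigma^2_bin(d) / sigma^2_landscape``.
3. Fit the NK-model reference decay ``f(x) = (1 - x/N) (1 - k/N)^x`` with
   N fixed (default 700) by nonlinear least squares; the fitted k is the
   ruggedness coefficient.  k = 0 is an additive (smooth) landscape; larger
   k means more, and more-isolated, local optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .landscape import Landscape, grid_sample

try:  # compiled pair loop; a chunked numpy path covers numba-less installs
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "DEFAULT_BIN_EDGES",
    "DEFAULT_N_REF",
    "BinnedVariance",
    "AutocorrelationCurve",
    "RuggednessFit",
    "DegenerateLandscapeError",
    "binned_pairwise_variance",
    "autocorrelation",
    "nk_reference",
    "fit_k",
    "quantify_ruggedness",
    "curve_to_table",
]

DEFAULT_BIN_EDGES = tuple(float(e) for e in range(0, 800, 100))
DEFAULT_N_REF = 700.0
DEFAULT_CHUNK_SIZE = 512


class DegenerateLandscapeError(ValueError):
    """Raised when the landscape variance is zero (constant fitness)."""


@dataclass(frozen=True)
class BinnedVariance:
    """Per-distance-bin mean squared fitness differences.

    ``mean_sq_diff`` is NaN for bins containing no pairs.  The raw per-bin
    sums are kept alongside the means so that streaming accumulation can be
    checked exactly against a brute-force pair enumeration.
    """

    bin_edges: np.ndarray
    sq_diff_sums: np.ndarray
    pair_counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def mean_sq_diff(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.pair_counts > 0,
                self.sq_diff_sums / np.maximum(self.pair_counts, 1),
                np.nan,
            )


@dataclass(frozen=True)
class AutocorrelationCurve:
    """Normalized landscape autocorrelation per distance bin.

    ``norm_bin_index`` marks the bin whose mean squared difference served
    as the landscape-variance normalizer (its LA is 0 by construction);
    None for synthetic curves that were not normalized from binned data.
    """

    bin_midpoints: np.ndarray
    la_values: np.ndarray
    sigma2_landscape: float
    norm_bin_index: int | None = None


@dataclass(frozen=True)
class RuggednessFit:
    k: float
    n_ref: float
    residual_sum_sq: float
    converged: bool
    n_bins_used: int


def _validate_edges(bin_edges) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("bin_edges must be a 1-D array with at least 2 entries")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    return edges


def _accumulate_pairs_py(pts, fit, edges, sums, counts):
    # streaming accumulation over all unordered pairs in lexicographic
    # (i, j>i) order; [lo, hi) bins with the final bin closed at the top
    n = pts.shape[0]
    ndim = pts.shape[1]
    nbins = edges.shape[0] - 1
    for i in range(n - 1):
        for j in range(i + 1, n):
            dsq = 0.0
            for d in range(ndim):
                diff = pts[i, d] - pts[j, d]
                dsq += diff * diff
            dist = np.sqrt(dsq)
            if dist < edges[0] or dist > edges[nbins]:
                continue
            if dist == edges[nbins]:
                b = nbins - 1
            else:
                b = nbins - 1
                for m in range(nbins):
                    if dist < edges[m + 1]:
                        b = m
                        break
            fd = fit[i] - fit[j]
            sums[b] += fd * fd
            counts[b] += 1


if _HAVE_NUMBA:
    _accumulate_pairs = njit(cache=True)(_accumulate_pairs_py)
else:  # pragma: no cover
    _accumulate_pairs = None


def _bin_pair_block(d, sq, edges, n_bins, sums, counts):
    # [lo, hi) bins; the final bin is closed at the top edge.  Pairs beyond
    # the last edge are discarded.
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[d == edges[-1]] = n_bins - 1
    keep = (idx >= 0) & (idx < n_bins)
    if not np.all(keep):
        idx = idx[keep]
        sq = sq[keep]
    counts += np.bincount(idx, minlength=n_bins)
    sums += np.bincount(idx, weights=sq, minlength=n_bins)


def binned_pairwise_variance(
    points,
    fitnesses,
    bin_edges=DEFAULT_BIN_EDGES,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    subsample_pairs: int | None = None,
    seed: int | None = None,
) -> BinnedVariance:
    """Bin all unordered point pairs by distance; average squared fitness diffs.

    The full pair enumeration (the default) streams per-bin (sum, count)
    accumulators over all unordered pairs, visited in the lexicographic
    (i, j>i) order a nested loop would use (compiled loop when numba is
    available, chunked numpy otherwise).  With ``subsample_pairs`` set, a
    uniform random subset of pairs is used instead — an *approximation*
    intended for quick exploratory runs.
    """
    pts = np.asarray(points, dtype=float)
    fit = np.asarray(fitnesses, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (n, dimensions)")
    n = len(pts)
    if n < 2 or len(fit) != n:
        raise ValueError("need >= 2 points with one fitness value each")
    edges = _validate_edges(bin_edges)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    if subsample_pairs is not None:
        if subsample_pairs < 1:
            raise ValueError("subsample_pairs must be >= 1")
        rng = np.random.default_rng(seed)
        got = 0
        while got < subsample_pairs:
            m = subsample_pairs - got
            i = rng.integers(0, n, m)
            j = rng.integers(0, n, m)
            ok = i != j
            i, j = i[ok], j[ok]
            if len(i) == 0:
                continue
            dsq = np.zeros(len(i))
            for d in range(pts.shape[1]):
                dsq += (pts[i, d] - pts[j, d]) ** 2
            _bin_pair_block(np.sqrt(dsq), (fit[i] - fit[j]) ** 2, edges, n_bins, sums, counts)
            got += len(i)
        return BinnedVariance(edges, sums, counts)

    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if _HAVE_NUMBA:
        _accumulate_pairs(
            np.ascontiguousarray(pts), np.ascontiguousarray(fit), edges, sums, counts
        )
        return BinnedVariance(edges, sums, counts)
    col_index = np.arange(n)
    for i0 in range(0, n - 1, chunk_size):
        i1 = min(i0 + chunk_size, n)
        rows = np.arange(i0, i1)
        dsq = np.zeros((len(rows), n))
        for d in range(pts.shape[1]):
            dsq += (pts[rows, d][:, None] - pts[None, :, d]) ** 2
        mask = col_index[None, :] > rows[:, None]
        dist = np.sqrt(dsq[mask])
        sq = (fit[rows][:, None] - fit[None, :])[mask] ** 2
        _bin_pair_block(dist, sq, edges, n_bins, sums, counts)
    return BinnedVariance(edges, sums, counts)


def autocorrelation(binned: BinnedVariance) -> AutocorrelationCurve:
    """Normalize binned variances into a landscape-autocorrelation curve.

    The landscape variance is approximated by the farthest non-empty bin's
    mean squared difference, so that bin's LA value is exactly 0.
    """
    mean = binned.mean_sq_diff
    nonempty = np.nonzero(binned.pair_counts > 0)[0]
    if len(nonempty) == 0:
        raise DegenerateLandscapeError("no pairs fell inside the distance bins")
    norm_idx = int(nonempty[-1])
    sigma2 = float(mean[norm_idx])
    if not (sigma2 > 0):
        raise DegenerateLandscapeError(
            "landscape variance is zero in the normalization bin; a constant "
            "landscape has undefined autocorrelation"
        )
    la = 1.0 - mean / sigma2
    return AutocorrelationCurve(
        bin_midpoints=binned.bin_midpoints,
        la_values=la,
        sigma2_landscape=sigma2,
        norm_bin_index=norm_idx,
    )


def nk_reference(x, k, n_ref: float = DEFAULT_N_REF):
    """NK-model autocorrelation decay ``(1 - x/N) (1 - k/N)^x``.

    ``x`` is a distance in [0, N]; ``k`` is the interaction order in
    [0, N).  Accepts scalars or arrays of x.
    """
    xs = np.asarray(x, dtype=float)
    if n_ref <= 0:
        raise ValueError(f"n_ref must be > 0, got {n_ref}")
    if np.any(xs < 0) or np.any(xs > n_ref):
        raise ValueError(f"x must lie in [0, {n_ref}]")
    if not (0 <= k < n_ref):
        raise ValueError(f"k must lie in [0, {n_ref}), got {k}")
    out = (1.0 - xs / n_ref) * (1.0 - k / n_ref) ** xs
    return out if out.ndim else float(out)


def fit_k(
    curve: AutocorrelationCurve,
    n_ref: float = DEFAULT_N_REF,
    include_norm_bin: bool = False,
) -> RuggednessFit:
    """Least-squares fit of the NK reference curve; returns the best k.

    The normalization bin carries LA = 0 by construction and is excluded
    from the residual by default (``include_norm_bin=True`` keeps it).
    Multi-start (k0 in {0.1, 1, 8}) guards against local minima; the best
    residual wins, ties going to the smallest k.
    """
    keep = ~np.isnan(curve.la_values)
    if not include_norm_bin and curve.norm_bin_index is not None:
        keep[curve.norm_bin_index] = False
    x = curve.bin_midpoints[keep]
    y = curve.la_values[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 non-missing bins to fit k, have {len(x)}")

    upper = n_ref * (1.0 - 1e-12)

    def residuals(kv):
        return (1.0 - x / n_ref) * (1.0 - kv[0] / n_ref) ** x - y

    best = None
    for k0 in (0.1, 1.0, 8.0):
        res = least_squares(
            residuals,
            x0=[min(k0, upper)],
            bounds=([0.0], [upper]),
            xtol=1e-12,
            ftol=1e-14,
            gtol=1e-14,
        )
        ssq = float(np.sum(res.fun**2))
        cand = (ssq, float(res.x[0]), bool(res.success))
        if best is None:
            best = cand
        else:
            # ties on the residual go to the smaller k
            if ssq < best[0] - 1e-12 * (1.0 + best[0]) or (
                abs(ssq - best[0]) <= 1e-12 * (1.0 + best[0]) and cand[1] < best[1]
            ):
                best = cand
    ssq, k, ok = best
    return RuggednessFit(
        k=k, n_ref=float(n_ref), residual_sum_sq=ssq, converged=ok, n_bins_used=len(x)
    )


def quantify_ruggedness(
    landscape: Landscape,
    points_per_axis: int = 200,
    bin_edges=DEFAULT_BIN_EDGES,
    n_ref: float = DEFAULT_N_REF,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> RuggednessFit:
    """Full ruggedness pipeline with the default protocol.

    Grid-sample the landscape (200 x 200 by default), bin all pairwise
    squared fitness differences by distance, normalize to an
    autocorrelation curve, and fit the NK coefficient k.  Deterministic.
    """
    points, fits = grid_sample(landscape, points_per_axis)
    binned = binned_pairwise_variance(points, fits, bin_edges, chunk_size=chunk_size)
    curve = autocorrelation(binned)
    return fit_k(curve, n_ref=n_ref)


def curve_to_table(binned: BinnedVariance, curve: AutocorrelationCurve) -> pd.DataFrame:
    """Tabular export of the autocorrelation analysis (TSV-ready)."""
    return pd.DataFrame(
        {
            "bin_lo": binned.bin_edges[:-1],
            "bin_hi": binned.bin_edges[1:],
            "midpoint": binned.bin_midpoints,
            "pair_count": binned.pair_counts,
            "mean_sq_diff": binned.mean_sq_diff,
            "la_value": curve.la_values,
        }
    )
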