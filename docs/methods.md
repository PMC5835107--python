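# Methods

## Model landscapes

A landscape maps a point in multi-gene expression space to a scalar system
performance. We model landscapes as sums of axis-aligned Gaussian
sub-peaks,

    f(p) = Σ_j A_j exp( − Σ_d (p_d − c_jd)² / (2 s_jd²) ),

over a bounded domain (default two dimensions, [0, 1000]² "expression
units"). Axis-aligned (diagonal) covariance only: ruggedness is controlled
by per-axis spreads, and rotated peaks would add parameters the model does
not need. The formula is defined on all of R^d; bounds constrain samplers,
never evaluation — so no clamping artifacts enter the fitness values.

The built-in trio (`smooth`, `medium`, `rugged`) shares one table of 12
sub-peak centers and heights (heights 0.45–1.0, a unique highest peak near
the domain center, secondary optima spread over the domain) and differs
only by a per-landscape spread scale: 150.7, 124.314 and 97.759 units. The
scales were calibrated once, by bisection against the default
quantification protocol below, to ruggedness coefficients k ≈ 0.832, 1.07
and 2.07 — a series spanning "nearly additive" to "strongly multi-peaked".
The calibration is frozen in code; it is a property of the fixtures, not a
tunable.

Two cautions from the calibration. First, k is *not* monotone in the
spread scale over its whole range: at very large spreads the sub-peaks
merge into one broad dome and the fitted k creeps up again. The smooth
scale sits on the well-behaved descending branch. Second, with overlapping
peaks the global maximum exceeds the largest amplitude and shifts away
from that peak's center (`global_maximum` finds it by dense grid search
plus bounded local refinement).

## Ruggedness quantification

The pipeline follows the landscape-autocorrelation approach, adapted to
continuous (expression-level) rather than discrete (sequence) variables:

1. **Grid sample** — an evenly spaced, endpoint-inclusive grid, default
   200 × 200 (40,000 points; spacing = range/199).
2. **Pairwise binning** — every unordered pair contributes its Euclidean
   distance and squared fitness difference; pairs are binned by distance
   into 0–100, 100–200, …, 600–700 (half-open [lo, hi), last bin closed;
   pairs beyond 700 discarded, since the finite 1000 × 1000 domain
   under-samples long distances). The per-bin mean squared difference is
   an (unnormalized) variogram.
3. **Normalization** — the farthest non-empty bin's mean approximates the
   landscape variance σ²_landscape, giving LA(d) = 1 − σ²_bin(d)/σ²_landscape.
   That bin's LA is identically 0 by construction; it is excluded from the
   fit by default (`include_norm_bin` restores it). A constant landscape
   has zero variance and raises a degenerate-landscape error rather than
   returning a meaningless curve.
4. **NK fit** — nonlinear least squares of f(x) = (1 − x/N)(1 − k/N)^x,
   N = 700 fixed, over the bin midpoints (50, 150, …), k constrained to
   [0, N). Multi-start at k₀ ∈ {0.1, 1, 8} guards against local minima;
   ties on the residual go to the smallest k. The factor-of-two relation
   between mean squared pairwise difference and variance cancels in the
   LA ratio and needs no correction.

The fit is unweighted (bins carry equal weight regardless of pair count);
at grid sampling densities every retained bin holds millions of pairs, so
count-weighting would change nothing material.

**Cost and exactness.** 40,000 grid points give ~8·10⁸ pairs. The
accumulation streams per-bin (sum, count) in a numba-compiled loop that
visits pairs in plain nested-loop order, so the result is bit-identical to
a brute-force enumeration (the test suite checks this against an
independent nested-loop oracle); a chunked numpy path covers installs
without numba, identical in counts and equal in sums to rounding error
when chunked. A uniform pair-subsampling mode (seeded) exists for
exploratory runs and is labeled approximate. Full quantification of one
landscape takes tens of seconds on one CPU.

## Sampling

Designs are drawn from a scrambled Sobol sequence (scipy's engine), mapped
through the inverse standard-normal transform per coordinate, scaled by
the spread σ (interpreted as the per-dimension standard deviation of the
normal target), optionally multiplied by the Cholesky factor of a shape
matrix, translated to the center, and clipped componentwise to the domain.
Choices worth noting:

* Unit-cube values are nudged into (2⁻⁵³, 1 − 2⁻⁵³) before the inverse
  normal, which otherwise maps the endpoints to ±∞.
* Clipping (rather than rejection or reflection) keeps exactly n designs
  per iteration and leaves the Sobol stream untouched; near a boundary the
  cloud piles up on the edge, which mimics a hard expression floor/ceiling.
* Replicate-to-replicate variation comes solely from the scrambling seed;
  each replicate of a sweep cell derives its own seed, so runs are
  reproducible and order-independent.

## Optimization algorithms

All three share the loop: sample n designs around the center, evaluate,
select the top max(1, round(F·n)) by fitness (ties at the cutoff to the
lower sample index), update the center. Iteration 1 samples around the
start coordinates; the center's own fitness is recorded every iteration,
so a trace of I iterations carries I center fitnesses.

* **hill_climb** — center ← arithmetic mean of parents. The next center
  always lies in the parents' convex hull.
* **projection** — center ← previous + 2·(parent mean − previous). Moves
  twice as fast uphill and can leave the parents' hull (overshoot), which
  is the intended trade.
* **cma_es** — a deliberately simplified covariance-matrix-adaptation
  variant. Center ← fitness-weighted parent average, weights proportional
  to fitness after shifting the iteration's minimum parent fitness to
  zero (no negative weights; canonical rank-log weights are available via
  `weight_mode="rank"`). The sampling shape matrix updates as
  (1 − c₁ − cμ)·previous + cμ·(weighted parent covariance about the new
  center, in σ-normalized coordinates) + c₁·(outer product of the unit
  direction of the center move), with cμ = 0.5, c₁ = 0.2, then symmetrized
  and ridge-floored to stay positive-definite. σ itself is a fixed sweep
  parameter; only the shape adapts. This is *not* full CMA-ES — no
  step-size control, no evolution paths — just the two ideas the batch
  setting can use: track the parents' anisotropy and prefer the direction
  of recent progress.

A known consequence of this design, measured by the package's own sweeps
at the reduced scale below: the covariance variant's best 5-iteration mean
performance matches or slightly exceeds projection's on all three model
landscapes (its weighted center plus focused sampling moves essentially as
fast), while with 20 iterations it reliably reaches the smooth landscape's
global maximum. Larger-scale comparisons, or variants with deliberately
conservative recombination, could order these algorithms differently;
surveys of this family in the literature have reported the covariance
strategy as the slower one over five iterations.

## Scoring and sweeps

* **performance** = Σ over iterations of the center fitness (rectangle
  rule, unit spacing; a trapezoid switch exists and differs only in
  endpoint weights). It rewards both the level reached and the speed of
  getting there.
* **reliability** = sample standard deviation (n − 1) of performance over
  replicates. σ = 0 clouds are degenerate-deterministic and give 0.
* **parameter_sweep** runs a full factorial (σ, F) lattice, default
  σ ∈ {50, 100, 200, 400}, F ∈ {0.1, 0.2, 0.4, 0.8}, 5 replicates per
  cell, seeds derived per (cell, replicate) from the base seed via
  numpy's SeedSequence spawn keys — embarrassingly parallel by contract,
  identical results regardless of execution order.

Default sweep conditions used throughout tests and the acceptance script:
start (300, 700), n = 50 designs/iteration, I = 5, base seed fixed. These
sizes keep a full 3-algorithm × 3-landscape sweep set under a minute while
leaving each cell's replicate noise well below the between-cell contrasts
of interest.

## What the synthetic landscapes do and do not capture

The Gaussian-sum surfaces emulate the *topology* knob that matters for
batch optimizers — the number, width and separation of optima — under a
perfectly noise-free, static, two-dimensional fitness function. They do
not model measurement noise, biological replicate variation, genetic
context effects (which add "apparent ruggedness" on top of true epistasis),
asymmetric or higher-dimensional interactions, or landscapes that drift as
strains adapt. Passing tests therefore demonstrate algorithmic behavior on
controlled topologies, not expected titer gains on any real pathway; on
real systems the local ruggedness should be re-estimated as the search
moves.

## Numerical and interface choices

* Landscape spec files are versioned JSON (`"format": 1`); floats
  round-trip exactly through `repr`-based JSON serialization.
* Batch and single-point evaluation share one kernel, so they are bitwise
  interchangeable.
* `fit_k` convergence uses xtol 10⁻¹², far inside the 10⁻⁹ k-tolerance the
  protocol requires; non-convergence is flagged on the result, never
  silent.
* Supplementary surface-definition scripts (literal peak tables in Python
  source) can be imported via `import_supplementary_surface`; the file is
  parsed as an AST, never executed.
* The CLI writes a manifest (version, argv, resolved config, seed, sha256
  digests) next to every output; feeding a manifest back through
  `--config` replays the run byte-identically.
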