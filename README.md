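# rugopt

Ruggedness-guided, high-throughput / low-iteration batch optimization of
multi-gene expression landscapes.

## The problem

Raising the titer of a multi-gene pathway is a multivariate optimization
problem: each gene's expression level is an axis of a design space, and the
measured output (titer, flux, sensor signal) is a fitness surface over that
space. Modern DNA assembly makes it cheap to build and test *many designs
per round*, but each design-build-test **iteration** stays expensive. The
algorithms that fit this cost structure sample a large batch per iteration
and run for very few iterations — the opposite regime from classical
function-evaluation-frugal optimizers.

How well such a search works depends on how **rugged** the landscape is:
smooth, single-domed surfaces tolerate broad sampling and aggressive moves,
while surfaces with many local optima punish them. `rugopt` packages both
halves of the workflow:

1. **Quantify ruggedness** of a landscape from sampled points, and
2. **run and score batch optimizers** across their parameter space, so the
   sampling spread and selection pressure can be matched to the measured
   ruggedness.

The package targets computational/synthetic biologists who want to simulate
and tune these strategies before committing wet-lab rounds.

## Models and statistics

**Landscapes** are sums of axis-aligned Gaussian sub-peaks over a bounded
expression space (default two genes on [0, 1000]²):

    f(p) = Σ_j A_j · exp( − Σ_d (p_d − c_jd)² / (2 s_jd²) )

Three built-in model landscapes (`smooth`, `medium`, `rugged`) share one
table of sub-peak locations and heights and differ only in the per-axis
spreads, giving a controlled ruggedness series.

**Ruggedness** is estimated by landscape autocorrelation analysis: sample a
200 × 200 grid, bin all ~8·10⁸ point pairs by Euclidean distance (0–100,
…, 600–700 units), and average the squared fitness difference per bin. The
farthest bin approximates the landscape variance σ²_landscape, giving the
autocorrelation

    LA(d) = 1 − σ²_{bin(d)} / σ²_landscape,

which is fitted by nonlinear least squares to the NK-model reference decay

    f(x) = (1 − x/N) · (1 − k/N)^x ,   N = 700.

The fitted `k` is the ruggedness coefficient: k = 0 is an additive (smooth)
landscape, larger k means more, and more-isolated, local optima. The
built-in trio measures k ≈ 0.83, 1.07 and 2.07.

**Optimizers.** All three algorithms iterate: draw `n` designs from a
scrambled Sobol sequence shaped into a normal cloud of spread σ around the
current center, evaluate them, select the top fraction `F` as parents, and
move the center:

* `hill_climb` — next center is the geometric center of the parents;
* `projection` — the hill-climb displacement is doubled (faster uphill,
  more prone to overshoot);
* `cma_es` — a simplified covariance-matrix-adaptation variant: a
  fitness-weighted parent average moves the center and the sampling cloud's
  shape adapts to the parents' spread and the direction of movement.

A run of `I` iterations (default 5) is scored by **performance** — the area
under the center-point fitness trajectory — and a (σ, F) cell of a
parameter sweep is scored by the mean and standard deviation
(**reliability**) of performance over 5 seeded replicates.

## Worked example

Quantify the medium model landscape at a reduced 100 × 100 grid:

```
$ rugopt ruggedness --landscape medium --points-per-axis 100 --out demo
k = 1.0539 (n_ref = 700, converged = True)
```

`demo.curve.tsv` holds the per-bin autocorrelation table and
`demo.fit.json` the fit report; k ≈ 1.05 marks a moderately rugged surface
(between the additive k = 0 and the built-in rugged trio member at ≈ 2.07).

Run one seeded projection search on it (start (300, 700), σ = 200 units,
50 designs/iteration, top 20% as parents):

```
$ rugopt optimize --landscape medium --algorithm projection \
      --sc 300,700 --sigma 200 --n 50 --fraction 0.2 --seed 7 --out demo_run
performance = 5.63991; final center fitness = 1.11977
```

Performance 5.64 is the sum of the five center fitnesses; the final center
sits at fitness 1.12 of a global maximum of ≈ 1.32. Sweep (σ, F) on the
rugged landscape to pick parameters:

```
$ rugopt sweep --landscape rugged --algorithm projection \
      --sigma 100,200,400 --fraction 0.1,0.2,0.4 --n 50 --replicates 5 \
      --seed 11 --out demo_sweep
best cell: sigma = 200, F = 0.1, mean performance = 4.06157 (+/- 0.599 over 5 replicates)
```

`demo_sweep.cells.csv` is the heatmap-ready per-cell table (mean
performance and reliability), `demo_sweep.replicates.csv` the per-replicate
long table. Note the best cell is also the least reliable one (sd 0.60) —
on rugged landscapes the aggressive settings gamble on which local optimum
they commit to. Every command writes a `*.manifest.json` (tool version,
resolved configuration, seed, output digests); passing a manifest back via
`--config` reproduces the outputs byte-for-byte.

## Layout

| module | role |
| --- | --- |
| `rugopt.landscape` | Gaussian-sum landscapes, spec-file I/O, grid sampling, built-in trio |
| `rugopt.ruggedness` | pairwise distance binning, autocorrelation, NK-model k fit |
| `rugopt.sampling` | seeded scrambled-Sobol engine, normal-shaped design clouds |
| `rugopt.optimizers` | the three batch algorithms and the iteration trace |
| `rugopt.evaluation` | performance/reliability scoring, (σ, F) parameter sweeps |
| `rugopt.cli` | `rugopt` umbrella command (landscape / ruggedness / optimize / sweep) |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical choices.
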