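# overlapmodel

Log-linear modeling of genomic interval overlap with any number of
reference interval sets.

## The problem

A recurring question in regulatory genomics: do the locations of a set of
*query* intervals — retrotransposon insertion sites, variant positions,
binding events — associate with one or more *reference* feature sets
(histone-mark peaks, gene bodies, lamina-associated domains, replication
timing, ...)? Classical overlap tests (shuffle-based or analytical) are
pairwise: query against one reference set at a time. They cannot see
higher-order structure, such as an enrichment in gene bodies *only when*
those genes also carry a repressive mark, and they routinely misattribute
an effect to a feature that merely co-locates with the true driver.

`overlapmodel` instead puts a single probability model on query location.
For a query interval q(x, y) = {x, ..., x+y−1} with start X and length Y
on a genome G = {1, ..., L}, the conditional density of the start is an
exponential tilt of a uniform null f₀ on the mappable start domain G₀(y):

    f(x | y) = c(θ, y) · f₀(x | y) · exp( Σ_π θ_π r_π(x | y) )

where π ranges over non-empty subsets of the N reference sets,
r_π(x|y) = Π_{i∈π} r_i(x|y) indicates simultaneous overlap of q(x, y) with
every R_i, i ∈ π, and c(θ, y) normalizes. The enrichment profile
h(x|y) = Σ_π θ_π r_π(x|y) has a direct reading: relative to a background
start (one overlapping nothing), a start position is enriched by the
factor e^h. A coefficient θ_π ≠ 0 is an effect of the *combination* π
beyond its lower-order parts.

The package provides:

- **exact interval algebra** (merge, left-dilation, erosion, intersection,
  complement) on 1-based inclusive coordinates, with BED3/chrom.sizes I/O;
- **the overlap partition**: a boundary sweep that cuts G₀(y) into at most
  2^N constant-pattern cells with sizes m_v(y), reducing every genome-wide
  sum to a sum over realized cells;
- **maximum likelihood**: the working log-likelihood
  ℓ(θ) = θ′T + Σ_i log c(θ, y_i) (T the per-term overlap counts) is
  concave; a damped Newton iteration finds θ̂, with Wald confidence
  intervals from the observed information and explicit detection of
  divergent fits (θ̂_π → ±∞ when t_π = 0 or nested counts tie);
- **inference and selection**: per-term generalized likelihood-ratio tests
  (χ²₁), BIC = d·log n − 2ℓ(θ̂), bidirectional stepwise search over a
  candidate term universe, and primary/secondary effect labeling;
- **simulation**: exact-cell and acceptance/rejection samplers drawing
  i.i.d. queries from the model, plus study drivers for estimator
  recovery, selection performance, and convergence rates, and a seeded
  generator of identifiable synthetic reference geometries;
- **diagnostics**: identifiability (rank of the pattern design; for the
  full model, all 2^N cells non-empty) and feasibility (which sufficient
  statistics predict divergence) checks, runnable before any fit.

## Worked example

```python
import numpy as np
import overlapmodel as om

layout = om.GenomeLayout([("chr1", 500_000)])
refs = om.synth_references(layout, 2, 150, 500.0, seed=42)
mappable = om.IntervalSet.whole_genome(layout)

spec = om.ModelSpec(2, [[1], [2], [1, 2]])
truth = np.array([1.0, 0.5, -1.0])
queries = om.sample_queries(truth, spec, refs, mappable, layout,
                            om.SimOptions(seed=7, n=2000))
data = om.OverlapDataset.from_queries(queries, refs, mappable, layout)
fit = data.fit(spec, with_ci=True)
```

Printing the fit (see `examples/fit_known_terms.py`) gives:

```
converged: True   log-likelihood: 161.53
    term   truth  theta_hat               95% CI   p (GLRT)
     {1}    1.00     1.0162 [  0.9103,   1.1221]   6.95e-68
     {2}    0.50     0.4843 [  0.3637,   0.6048]   5.06e-14
   {1,2}   -1.00    -1.0817 [ -1.4016,  -0.7618]   2.60e-13
```

Each interval brackets its simulation truth. The positive main effects
say queries co-occur with each reference set more than a uniform null
predicts (e^1.02 ≈ 2.8-fold for set 1 alone); the negative interaction
says the joint overlap is less enriched than the two main effects would
multiply to (h = 1.02 + 0.48 − 1.08 ≈ 0.42 for starts overlapping both).

The `examples/` directory has one short script per capability: fitting,
stepwise selection, sampler cross-checks, identifiability/feasibility
diagnostics, and recovery/convergence studies. A thin CLI
(`overlapmodel fit|select|simulate|study|check|synth`) exposes the same
operations on BED files from the shell.

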