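# Methods

## Model

Let G = {1, ..., L} be the concatenated locus space of a genome (each
chromosome an independent segment; nothing spans a boundary) and
R_1, ..., R_N normalized reference interval sets. A query interval
q(x, y) = {x, ..., x+y−1} overlaps R_i iff their intersection is
non-empty; r_i(x|y) is that indicator and r_π(x|y) = Π_{i∈π} r_i(x|y) the
joint indicator for a term π ⊆ {1..N}. Conditional on the length Y = y,
the start X has density

    f(x|y) = c(θ, y) f₀(x|y) exp( Σ_π θ_π r_π(x|y) ),

an exponential-family tilt of the null f₀. The null used throughout is
uniform on the mappable start domain G₀(y) = {x : q(x, y) ⊆ M}, M the
user-supplied mappable region (default: the whole genome). Every θ_π is
unconstrained in ℝ; the model with all 2^N − 1 terms is the "full" model.

Interpretation runs through the enrichment profile h(x|y) = Σ_π θ_π r_π:
for mappable x and a background x̃ (overlapping nothing), f(x|y)/f(x̃|y) =
e^{h(x|y)}, so h > 0 means enrichment, h < 0 depletion, and h sums the
coefficients of exactly those terms whose sets are all overlapped at x.

## Reduction to pattern cells

r(x|y) depends on x only through the N-bit overlap pattern
v(x) = (r_1, ..., r_N). The start domain G₀(y) therefore partitions into
at most 2^N cells of constant pattern, with sizes m_v(y), and

    c(θ, y)^{-1} = Σ_v (m_v(y)/|G₀(y)|) exp(θ·s(v)),   s(v)_π = Π_{i∈π} v_i.

Cells are built per chromosome by a sorted-boundary sweep over the
endpoints of G₀(y) and of the left-dilated references
D_i(y) = {x : q(x, y) ∩ R_i ≠ ∅} (each [a, b] of R_i grows to
[a−y+1, b], clipped at 1): between consecutive breakpoints the pattern is
constant and is read off the first base. Cost is O(B log B + B·N) in the
total breakpoint count B — never a per-base scan (per-base enumeration
exists only as the test oracle). Partitions are computed per distinct
query length, exactly conditioning on Y = y with no length binning; only
realized cells (m_v > 0) are stored, and N is capped at 20 by
configuration to bound pattern enumeration.

## Likelihood, estimation, and uncertainty

For n queries with conditionally independent starts, the working
log-likelihood after dropping θ-free log f₀ constants is

    ℓ(θ) = θ′T + Σ_i log c(θ, y_i),     t_π = Σ_i r_π(x_i|y_i),

so ℓ(0) = 0 identically and model comparisons (GLRT, BIC) are unaffected
by the dropped constants; all reported log-likelihoods use this
convention. ℓ is concave with score T − Σ_i E_θ[s(V)|y_i] and observed
information Σ_i Cov_θ[s(V)|y_i] (PSD). The MLE is found by damped Newton
ascent: ridge-regularized Newton directions, backtracking line search,
and two stopping rules — a gradient tolerance and a Newton-decrement
floor. Numerical choices that matter:

- the gradient tolerance is *relative*, ‖g‖∞ ≤ tol · max(1, ‖T‖∞) with
  tol = 1e-8: the objective is O(n), so an absolute cutoff stalls in
  float noise at realistic n;
- cell log-weights are renormalized by their own log-sum-exp at compile
  time (a mathematically exact shift) so that ℓ(0) = 0 holds to ~1e-15;
- log-sum-exp is used for every normalizer evaluation; |θ| is hard-capped
  at 30 during iteration to prevent overflow.

Divergence — a coefficient drifting to ±∞ — is detected, not returned
silently: a fit is flagged non-convergent when any |θ̂_π| ≥ 5 (the
threshold is configurable; 5 is the conventional cutoff for this model
family, where coefficients of genuine effects are order 1). The
feasibility check predicts divergence ahead of fitting: t_π = 0 for an
included term, or t_π = t_π̃ for nested included terms π̃ ⊂ π.

Confidence intervals are Wald-type, θ̂_π ± z_{1−α/2}·sqrt([I(θ̂)^{-1}]_ππ),
from the observed information — a design choice of this package; any
construction with the same asymptotics would do, since the MLE is unique
by concavity whenever the model is identifiable.

Identifiability is checked numerically: ℓ depends on θ only through
{θ·s(v)} over realized patterns, so the MLE is unique iff the stacked
design matrix of realized-pattern rows (pooled over query lengths) has
full column rank d. For the full model this reduces to all 2^N pattern
cells being non-empty.

## Testing and selection

The GLRT for θ_π = 0 refits with the term removed and refers
Λ = 2(ℓ_free − ℓ_constrained) to χ² with 1 degree of freedom (one scalar
constraint). Λ ≥ 0 is structural (nested models) and is clipped at 0
against float error. P-values are reported raw, with **no
multiple-testing correction** across terms — when many terms are
screened, calibrate expectations accordingly.

Model selection minimizes BIC = d log n − 2ℓ(θ̂), n the number of query
intervals, by bidirectional stepwise search: starting from the empty
model (BIC = 0 under the working-likelihood convention), every
single-term addition and removal is scored each round, the lowest-BIC
move is accepted iff it strictly improves, and the search stops when none
does. Strict improvement plus a finite candidate set rules out cycling.
Ties break deterministically: removal before addition, then smaller |π|,
then lexicographic — determinism matters more than the particular rule.
No hierarchy constraint is imposed (an interaction may enter without its
main effects, which is precisely what makes combination-only effects
discoverable). The candidate universe defaults to all 2^N − 1 terms and
can be restricted by maximum interaction order or an explicit list;
candidates with t_π = 0 are excluded up front, and non-convergent
candidate fits are skipped with a logged diagnostic. Selected significant
terms are labeled *primary* (no significant selected term is a proper
subset) or *secondary*.

## Simulation

Two samplers draw i.i.d. starts from f given lengths; both target the
identical law:

- **exact_cell** (default): draw a cell with probability
  ∝ m_v(y)·e^{θ·s(v)}, then a start uniform within the cell — exact and
  rejection-free;
- **acceptance_rejection**: propose uniform on G₀(y), accept with
  probability e^{h − h_max}; the acceptance probability is bounded below
  by e^{h_min − h_max} > 0, so the sampler cannot stall. Retained as an
  independent cross-check of the partition code (the two samplers are
  compared by chi-square homogeneity in the tests).

Query lengths default to fixed y = 1 in studies (the estimation problem
conditions on length, so fixing it isolates the geometry); a list of
lengths can be resampled with replacement instead.

Study drivers replay three protocols on any geometry: *estimation*
(simulate, fit the true model, summarize the replicate distribution of
θ̂, counting and excluding divergent replicates), *selection* (stepwise
per replicate; tabulate configuration percentages, per-term rates, exact
and superset recovery), and *convergence* (fraction of replicates with
all |θ̂| < 5, and the smallest n on a grid reaching a target rate).

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn`: geometry, per-replicate streams, and
sampler draws are independent, reproducible, and insensitive to replicate
order.

## Synthetic geometries: what they emulate, what they do not

`synth_references` drops a requested number of intervals (uniform starts
weighted by chromosome length; geometric lengths with requested mean) per
reference set, normalizes, and resamples up to a retry cap until every
2^N overlap-pattern cell is realized at y = 1, guaranteeing full-model
identifiability. A `nested_pair` option instead forces one set inside
another, producing the canonical non-identifiable pathology for negative
tests. `reference_summary` reports coverages and pairwise containment
fractions so fixtures can be matched to a desired structure.

The standard benchmark (`benchmark_geometry`): five sets on a 1 Mb
chromosome, 400 intervals of mean 600 b each (≈ 20% coverage apiece after
merging), fully mappable. The scale — 1 Mb rather than a real ~59 Mb
chromosome — was chosen so the full recovery (1000 replicates of
n = 2540) and selection (500 replicates, 31 candidates) studies run in
seconds; the estimator's behaviour depends on the geometry only through
the cell masses, which at 20% coverage are comfortably away from the
boundary, as on real chromatin-domain tracks.

What the synthetic generator does *not* emulate: the long-range
autocorrelation, clustering and mutual nesting structure of real
chromatin annotations, chromosome-specific coverage variation, and
realistic mappability gaps (the default is full mappability). Passing
recovery/selection studies on these fixtures therefore demonstrates
correctness of the estimator and search on an identifiable geometry of
realistic coverage — not robustness to every correlation structure real
tracks can exhibit. Exact percentage-level selection rates depend mildly
on geometry through the false-positive margin.

## Degenerate inputs and edge behaviour

- Empty G₀(y) (every mappable block shorter than y): degenerate-null
  error before any model computation.
- Queries starting outside G₀(y): rejected by default, or dropped with a
  count under an explicit option.
- Empty model (d = 0): fits trivially with ℓ = 0, BIC = 0.
- α = 1 Wald intervals have zero width at θ̂; singular information raises
  an identifiability error rather than returning garbage.
- Exactly-adjacent intervals merge during normalization (identical locus
  sets); BED scores/strands are ignored with a one-time warning — the
  model is strandless.

## Known limitations

- GLRT p-values are asymptotic (χ²₁); at very small n or tiny cell masses
  the null distribution is discrete and conservative/anticonservative
  behaviour is possible (the test suite checks approximate uniformity at
  n = 400).
- Fractional or weighted overlap is out of scope: r is binary by design.
- No penalized or Bayesian estimation; no FDR control across terms.
- Computation grows with the number of realized pattern cells (≤ 2^N per
  length) and with the candidate universe (2^N − 1 for unrestricted
  selection); for large N restrict by interaction order or a whitelist.
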