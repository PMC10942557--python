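# Methods

This note records the model, the numerical conventions, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Search model

The search operates on the *feasible set* of `p̄` variables retained after
candidate screening. Subsets of the feasible set are bitmasks over 0-based
feasible-set positions (original column order); the lattice is a hash map
keyed by bitmask. A node `v` may be appended to a nonempty subset `S` only
if `pp_v ∩ S ≠ ∅` — generational admissibility. This restricts expansion to
subsets lying on complete generational orderings and keeps the materialized
lattice far smaller than `2^p̄` whenever the candidate sets are sparse.

Full mode starts from the empty set; singletons score `local(v, ∅)`, so
every node can open an ordering as a root. Partial mode starts from every
subset of cardinality `p̄ − pOrd` with accumulated score 0: totals compare
only the contribution of the `pOrd` appended nodes, and the base's own best
sink is not added to the total (the base is context, not part of the
reported network). `pOrd = p̄` reduces exactly to full mode, which is tested
as an identity. If the top cardinality is unreachable (disconnected
candidate sets), results are reported at the maximum reached cardinality
with an explicit warning.

Reconstruction peels stored best sinks from the best top subset(s).
Floating-point ties: two scores tie when they differ by at most a relative
`1e-9`; at most 5 best sinks are stored per subset and at most
`max_networks` (default 10) equal-score networks are reconstructed. In
partial mode, base nodes referenced as parents are emitted as parentless
roots (`root_only_nodes`).

### Best-parents tables

`bestScore(v, U)`/`bestParents(v, U)` are defined by maximizing
`local(v, S)` over `S ⊆ U ∩ pp_v`, `|S| ≤ indegree`. Two equivalent routes
are implemented: an eager downward recurrence
`bestScore(v,U) = max(local(v,U), max_u bestScore(v, U\{u}))` over all pools
(used when `pp_v` is small), and a lazy memoized bounded enumeration of
combinations up to the in-degree cap, used by the search — eager tables over
all `2^|pp_v|` pools are infeasible when screening retains large candidate
sets at `p = 100`. The two routes are tested for exact agreement. Argmax
ties prefer the smaller cardinality, then the lexicographically smallest
subset in feasible-set order; comparisons in the tables are exact (no
epsilon), so pool-monotonicity holds exactly.

### Instrumented search-space counting

The expansion loop can propagate path counts: each appended sink multiplies
the count of its predecessor subset by the number of parent subsets the
tables would enumerate for its pool (with no in-degree cap, `2^k` for a pool
of size `k`; weight 1 counts orderings only). Summed over top-cardinality
subsets this yields the number of (ordering, parent-choice) combinations
the DP covers; on all-pairs candidate sets it equals
`Π_{k=p−r+1..p} k·2^(k−1)` for partial order `r`, which the tests verify
against an independent computation of the product. The instrumentation is
the authoritative count; no closed form is assumed.

## Scores

One BIC convention is used everywhere: maximized log-likelihood minus
`(k/2)·ln n`, so `−2·score` is classical BIC.

- **Gaussian (continuous child).** OLS with intercept; ML residual variance
  (divisor `N`); `k` = regression coefficients (intercept included) + 1 for
  the variance, i.e. `k = |parents| + 2` for continuous parents.
  Categorical parents enter as full dummy encodings (first level dropped)
  and contribute their dummy count to `k`. Residual variance below `1e-12`
  or a rank-deficient design yields a `−inf` sentinel with a warning.
- **Multinomial (categorical child).** `Σ_jk n_jk ln(n_jk/n_j·)` with
  `0·ln 0 := 0`; `k = (r−1)·Π_j q_j` over observed levels. Parent
  configuration spaces larger than `N` are allowed but warned (sparse
  tables). Continuous parents of a categorical child are rejected with a
  clear error; this keeps the score family well defined without a hybrid
  conditional-Gaussian model.
- **BGe.** Log marginal likelihood under the Gaussian–inverse-Wishart
  family, as the ratio of subset marginal terms (decomposable and
  score-equivalent). Hyperparameters: `α_μ = 1`, `α_w = p̄ + 2`, prior mean
  = sample mean (the mean-shift term vanishes), prior scale `T = t·I` with
  `t = α_μ(α_w − p̄ − 1)/(α_μ + 1)` — the de-facto default
  parameterization. Non-positive-definite posteriors yield `−inf`.
- **Outcome scores.** Continuous → Gaussian BIC. Binary → logistic
  log-likelihood − `(k/2)·ln N`, `k = |parents| + 1`; the fit carries a tiny
  quadratic regularizer (`1e-6`) so separated data give a finite score.
  Survival → Cox partial log-likelihood with Breslow ties (lifelines;
  null model computed directly as `−Σ_j d_j ln|R_j|`) − `(k/2)·ln(events)`,
  `k = |parents|`; penalizing by events rather than `N` reflects the
  effective information in censored data. Zero events or a single-class
  outcome yield `−inf`.

### Standardization

Residual-variance-based scores are not scale invariant, and in partial mode
the tail score has no compensating terms from the rest of the network: in a
linear cascade measured in raw units, upstream nodes have the smallest
conditional variances given their neighbours, which systematically biases
sink selection toward reversing edges. `discover` therefore z-scores
continuous columns (population sd) before scoring, making the discovered
structure independent of measurement units; this is also the setting in
which the BGe default prior `T = t·I` is sensible. It can be disabled with
`standardize=False`. Categorical and survival time/event columns are
untouched.

## Candidate screening

All unordered pairs are tested in one family — Pearson t-test
(continuous–continuous), chi-square (categorical–categorical), one-way
ANOVA F (mixed), univariate Cox Wald test (pairs involving a survival
outcome; strength = largest absolute standardized log-hazard) — then BH
adjusted; pairs with `q ≤ alpha` and association strength at least
`corr_floor` (default 0 = off) become mutual possible parents. Association
is undirected, so `pp` is symmetric except that a designated outcome is
never anyone's parent (pathways lead *to* the outcome; the outcome competes
naturally to be the final sink, with no extra forcing). Constant columns
are skipped with a warning. Phenotype-driven mode screens two generations
(outcome vs all; then the outcome's candidates vs all), BH-adjusted within
each stage's family, and keeps only the outcome, its candidates, and
theirs. Nodes with no candidate relations are dropped from the feasible
set; column order is preserved throughout, and no RNG is involved, so
screening is fully deterministic.

The FDR cutoff is applied globally (one family), not per node; in-degree is
enforced in the tables/search, not at screening time.

## Simulator

`simulate_dag` draws a connected subset of `p1 + p2 + p3` labels; orders it
sources first, intermediates, then sinks (uniform permutation within each
block); and gives each non-source connected node `1..max_parents` parents
(uniform) drawn from nodes above it in the ordering, excluding the sink
block — so sources/independents are parentless, sinks are childless, and
acyclicity holds by construction. Edge coefficients are uniform on
`[0.5, 1.5]` in absolute value with random sign — detectable but noisy
signal at `N ≥ 500`; roots are standard normal and children add
homoscedastic `N(0, 1)` noise (both configurable). Data generation follows
the topological order from a single seeded generator, so runs are
bit-reproducible.

What the generator emulates: a sparse three-generation pathway embedded
among independent variables, the regime the partial-orderings search
targets. What it does not emulate: non-Gaussian noise, latent confounders,
heteroscedasticity, discrete/mixed generating mechanisms, or dependence
among "independent" background variables. Passing grid tests therefore
demonstrate correct recovery behaviour under a linear-Gaussian
faithful-DAG model, not performance on arbitrary real data.

The benchmark harness assigns roles per cell as
`p1 = p2 = p3 = max(2, p // 10)` with the remainder independent — chosen
once as a realistic sparse-signal layout; replicate count defaults to 5 per
cell and is configurable.

## Evaluation

FDR `= FP/(FP+TP)` with `0/0 := 0` (an empty prediction makes no false
discoveries); structural Hamming distance `= FP + FN`. Directed mode
compares ordered pairs; undirected mode compares deduplicated skeletons;
false negatives are always counted against the full truth graph, including
in partial mode where the prediction is deliberately small. When the search
returns several tied networks the first (deterministic tie order) is
evaluated; a flag switches to averaging over ties. The grid harness clamps
`pOrd` to `p̄` when screening retains fewer nodes than the requested
ordering length (the search API itself rejects `pOrd > p̄`).

## Problem sizes

The test suite exercises exactness oracles at `p̄ ≤ 6` (where exhaustive
ordering enumeration is feasible) and the recovery grid at
`p ∈ {10,20,40} × N ∈ {500,1000,2000}` with 5 replicates per cell;
`scripts/acceptance.py` additionally runs `p ∈ {50,60,100}`. Grand means in
the acceptance script average three independently seeded repetitions of
each experiment, reducing Monte-Carlo error in the reported FDRs without
changing the estimand.

## Known limitations

- Directed-edge FDR is bounded below by score equivalence: edge pairs not
  disambiguated by a collider are oriented arbitrarily, and partial-mode
  tail scores can reward creating a collider at a true source with several
  children. Skeleton (undirected) FDR is the more faithful measure of
  adjacency recovery.
- Continuous parents of categorical children are unsupported (no
  conditional-Gaussian hybrid score).
- The BH screening family treats all pairs jointly; with very many null
  variables the feasible set still grows slowly with `alpha`.
- The lattice stores at most 5 tied sinks per subset, so in pathological
  all-tie instances not every optimal network is enumerated (the returned
  ones are all optimal).
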