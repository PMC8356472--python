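# Methods

## Feasibility of a missing correlation

A p×p correlation matrix R is valid when it is square, symmetric, has unit
diagonal, entries in [−1, 1], and is positive semidefinite. With exactly
one symmetric pair of cells unknown, the set of values completing R to a
valid matrix is a closed interval: the PSD cone is convex, and the
completion is affine in the missing value. `corbound` finds this interval
analytically rather than by search.

The route is the hypersphere parameterization of the Cholesky factor.
Cholesky–Crout computes L column by column from the upper-left corner:

    L[j,j] = sqrt(A[j,j] − Σ_{k<j} L[j,k]²)
    L[i,j] = (A[i,j] − Σ_{k<j} L[i,k]·L[j,k]) / L[j,j],   i > j.

When the missing pair sits at the anchor (p, p−1), only L[p, p−1] and
L[p, p] depend on it; everything else is computable. Writing each unit-norm
row of L in spherical coordinates gives the angle matrix θ with entries in
[0, π]; the missing correlation is monotone decreasing in its anchor angle,
so θ = 0 / π yield the maximum / minimum after back-conversion. The
algebraic identity

    bound = Σ_{k≤p−2} L[p,k] L[p−1,k] ± L[p−1,p−1] √(1 − Σ_{k≤p−2} L[p,k]²)

is used as an independent cross-check in the tests, never as the
implementation path.

A missing pair anywhere else is first moved to the anchor by symmetric
row/column swaps (a similarity transform: correlations, eigenvalues and the
diagonal are preserved). The swap rule is deterministic: an index already in
{p−1, p} stays put and the other index is swapped in (one swap); otherwise
the smaller index goes to p and then the larger to p−1 (two swaps, the order
the worked example uses). At most two swaps are ever needed; the rule is
property-tested by enumerating every lower-triangle position for p ≤ 6.

### Numerical choices

- **PSD tolerance** `psd_tol = 1e−8`: eigenvalues ≥ −1e−8 count as
  nonnegative. Interval endpoints produce exactly singular completions, so
  a zero cutoff would misclassify them under rounding.
- **Pivot tolerance** `chol_tol = 1e−12`: a diagonal radicand in
  (−1e−12, 1e−12] is clamped to 0 (semidefinite pivot); entries below a zero
  pivot are set to 0, the convention that a fully determined variable leaves
  no freedom. A radicand below −1e−12 raises an error naming the column.
- **Angle recursion degeneracy**: when a running sine product falls below
  1e−12 the remaining angles in the row are set to 0. Any angle maps to the
  same matrix at that point; 0 is the deterministic tie-break. Consequently
  a degenerate problem returns a zero-width interval (lo = hi), not an
  error.
- **arccos clamping**: arguments within 1e−9 of ±1 are clamped; beyond that
  band the factorization and the recursion disagree and an error is raised.
- **Invalid observed part**: if the observed submatrix is itself not PSD
  (possible with pooled empirical matrices) the solver raises rather than
  repairing; nearest-correlation-matrix projection is out of scope.
- Indexing in every public interface and error message is 1-based
  (row, column), the convention of the matrix-language ecosystem this
  mirrors; storage is 0-based numpy.

### Brute-force oracle

`boundary_oracle` scans candidate values over [−1, 1] on a fixed grid,
completes the matrix with each, and keeps those whose smallest eigenvalue is
≥ −psd_tol. It shares no code with the analytic path (no swaps, no
Cholesky, no angles) and bounds the analytic result within one grid step.
The eigenvalue scan is batched over the whole candidate grid for speed.

## Imputation over the interval

The sampling distribution is piecewise uniform over *fractions* of the
feasible interval: breakpoints 0 = b₀ < … < b_K = 1 and one nonnegative
weight per sub-interval summing to 1. A draw selects a sub-interval by its
weight, then samples uniformly within it; the fraction f maps to
lo + f·(hi − lo). Point methods `min`, `max`, `midpoint` need no
randomness. All randomness flows through an explicit seeded
`numpy.random.Generator`; there is no global RNG state.

One interface note: a distribution over K sub-intervals requires exactly K
weights. A specification that pairs K+1 breakpoints with K−1 weights (e.g.
breakpoints (0, .4, .8, 1) with weights (.2, .8), intending zero mass in
the middle) must be written explicitly as (.2, 0, .8) here — stricter but
unambiguous.

With several missing pairs, `sequential=True` completes them one at a time,
narrowest interval first, each sub-problem formed by dropping one index of
every other missing pair. This is a documented heuristic: it guarantees a
valid completed matrix but explores no joint feasible region, and the
result depends on the imputation order it induces.

## Synthetic valid matrices

`random_valid_matrix` draws each lower-triangle angle independently as
arccos(U), U ~ Uniform(−1, 1), and back-converts. Every draw is a valid
correlation matrix with angles in the open interval, giving a good spread
of both well- and ill-conditioned fixtures (the induced first-column
correlations are uniform; deeper entries concentrate mildly). It makes no
claim of uniformity over the elliptope — LKJ/onion-style uniform samplers
are out of scope — so test results weight regions of the elliptope
differently than a uniform law would.

## Pooling simulation

The generator emulates a meta-analysis of correlation matrices: each study
draws N ~ Normal(100, 20) observations (rounded, floored at n_min = 10;
the rounding and floor are our choices, the scale is the study condition)
from a 4-variable multivariate normal with mean zero and population
correlation matrix

    Σ = [[1, .5, .5, 0], [.5, 1, .5, .3], [.5, .5, 1, −.1], [0, .3, −.1, 1]],

computes the sample Pearson correlation matrix, and injects missingness:
either one uniformly-chosen lower-triangle pair per study (experiment 1) or
the fixed (2, 1) cell missing with probability p (experiment 2). What this
emulates — and what it does not: real studies differ in populations and
measurement error, and real missingness is rarely at random; passing tests
show estimator behavior under ideal MVN sampling only.

Estimators pool cellwise over the studies observing a cell:

- `avg` — unweighted mean;
- `fisher_weight` — weighted mean of atanh(r) with weight N − 3 (the
  reciprocal sampling variance of Fisher's z), back-transformed by tanh;
- `var_weight` — weighted mean of raw r with weight var(r)^(−q),
  var(r) = (1 − r²)² / (N − 1); q defaults to 2, reading "reciprocal
  square" literally, with q = 1 (standard inverse variance) available via
  `weight_exponent`. The study's own r enters the variance formula, with
  |r| clipped at 0.999 so weights stay finite;
- `zero` — missing cells replaced by 0 within each study, then an
  unweighted mean over all studies.

Pooled matrices are not projected to PSD; the MSE is cellwise (mean over
the p(p−1)/2 strictly-lower-triangle cells, or the single fixed cell in
experiment 2).

Empty cells: `pool()` errors when a cell is observed in zero studies under
a data-dependent estimator. Experiment 1 instead pools such a cell as 0
for all estimators (at n = 1 every replication has one, so erroring or
redrawing would leave the small-n end of the grid undefined). Experiment 2
redraws the whole replication whenever the fixed cell is missing in all 10
studies — at p = 0.8 this happens with probability 0.8¹⁰ ≈ 0.107 — and
reports the redraw count; redrawing for all four estimators keeps the
comparison paired on identical data.

Experiment defaults are 1,000 replications. The test suite and examples
run the experiments at 200 and 50 replications respectively — sizes at
which the estimator orderings the study design probes (Fisher-z weighting
at or below zero imputation for n ≥ 5; at or below the unweighted average
at 80% missingness) are stable across seeds, as the deeper tests verify.

## Known limitations

- Exactly one missing pair per boundary solve; the sequential mode is a
  heuristic, not joint feasibility.
- The fixture generator is not uniform over the elliptope.
- The variance formula var(r) = (1 − r²)² / (N − 1) is the large-sample
  approximation; no small-sample correction is applied.
- Stochastic imputation reproduces a given seed of numpy's PCG64 stream
  only; streams of other environments' RNGs are not matched.
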