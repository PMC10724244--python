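# Methods

## The statistic

For a symmetric dissimilarity matrix `D` over `n` observations and a label
vector `L`, the upper-triangle distances split into the within-cluster set
`D_W` (both endpoints share a label) and the between-cluster set `D_B`;
`|D_W| + |D_B| = N_d = n(n-1)/2` and `alpha = |D_W| / N_d`.  The raw
discordance `s` counts cross pairs `(w, b)` with `w > b` *strictly*; ties
contribute nothing.  Ties are nevertheless counted and reported as a
diagnostic, because heavily tied inputs (e.g. the binary metric on sparse
indicator data) make the strict count hard to interpret.

`H+ = s / (|D_W| |D_B|)` estimates `P(w > b)` without bias and without any
dependence on `alpha`; `G+ = s / (N_d (N_d-1)/2)` is kept for comparison and
satisfies `E[G+] = (N_d/(N_d-1)) * 2 alpha (1-alpha) * P(w > b)`.  The
balance identity `alpha = (1/(n-1)) * sum_j b_j (n b_j - 1)` is exact for
integer group sizes `n b_j`; fractional sizes are accepted as the continuous
extension of the same formula (useful for planning), while every empirical
alpha in the package comes from integer counts.

`s` is computed by sorting the between set once and binary-searching each
within value (`O(N_d log N_d)`), which is exactly equivalent to the
quadratic double loop; the double loop is retained as a test oracle, and
the count is cross-checked against the Mann-Whitney U statistic.

Degenerate partitions — a single cluster (no between distances) or
all-singleton labels (no within distances) — leave H+ undefined; the
package raises a `DegeneratePartitionError` carrying the still-defined
quantities (`s`, `G+`, `alpha`) rather than returning NaN.  G+ itself is 0
there by construction.  The experimental penalised variants divide H+ by
`max(alpha, 1-alpha)` (penalising one giant cluster) or `min(alpha,
1-alpha)` (penalising many tiny clusters; can exceed 1) and are flagged as
experimental.

On ingestion, matrices asymmetric beyond a relative tolerance of 1e-8 are
rejected; asymmetry within tolerance is averaged away and the diagonal
zeroed, since the statistic presumes a proper dissimilarity.

## Quantile-sketch estimation (HPE)

Each distance set is summarised by `p + 1` percentile values at levels
`i/p`, `i = 0..p`, computed by linear interpolation between order statistics
(so the endpoints are exactly the minimum and maximum; the interpolated
estimator is continuous in the data, which any estimator satisfying the
endpoint condition and monotonicity could replace without changing the
guarantees).

Both estimators assign each within-percentile column `i` the increment
`z_i = j / p^2` where `q(D_B)_j < q(D_W)_i <= q(D_B)_{j+1}` — 0 below the
between minimum, `1/p` above the between maximum.  Equivalently, column `i`
counts the *upper bin edges* `q(D_B)_1 .. q(D_B)_p` it strictly exceeds.
The brute-force algorithm evaluates all columns against the sorted sketch
(`O(p^2)` comparisons in the nominal formulation; binary search in
practice); the grid search walks the monotone boundary of the
greater/not-greater grid in `O(p)` comparisons, and columns the walk never
reaches (the between index exhausts first) receive the terminal increment.
The two algorithms produce bit-identical values; the sum is clipped to
[0, 1] (the raw count can exceed `p^2` when almost — but not quite — every
sketch value of `D_W` dominates `D_B`, in which case the exact H+ is also
near 1).  Disjoint-support inputs short-circuit to exactly 0 or 1.

The bin-edge convention matters.  Counting *all* `p + 1` sketch values
(i.e. `z_i` one grid unit larger per nonzero column) inflates the estimate
by roughly `(1 + H+)/p`, which breaks the `|H+ - H_e| < 1/p` guarantee —
measured +0.0204 at `p = 50` on the overlapping-Gaussians example below,
versus -0.0001 under the bin-edge convention.  Per column the bin-edge
increment is within `1/p^2` of the column's true mass, and the summed error
over `p + 1` columns stays below `1/p` whenever the sketches actually carry
the sets' rank structure.  That qualifier is a real validity condition: if
`p` is comparable to or larger than `min(|D_W|, |D_B|)` (extreme case: one
within distance, whose sketch is constant) the error can touch `1/p`
exactly.  The estimator is meant for, and tested in, the regime
`2p <= min(|D_W|, |D_B|)` — trivially satisfied in practice, where distance
sets have `O(n^2)` elements — in which no violation was observed over
~20,000 randomized checks (worst observed error about `0.8/p`).

The default `p = 101` guarantees three-figure accuracy (< 0.0099) and is
exposed as a flag everywhere.

### gamma_W, gamma_B factorisations

A true comparison at walk cell `(i, j)` certifies that the top
`(1 - i/p)` fraction of `D_W` strictly exceeds the bottom `j/p` fraction of
`D_B`, i.e. the pair `(gamma_W, gamma_B) = (1 - i/p, j/p)` is empirically
verified.  `estimate_gammas` returns the verified pairs whose product lies
in `h_e ± 1/(p-1)` — the window radius follows the factorisation
construction and is deliberately not reconciled with the convergence bound
`1/p`.  Caveat: for any cut `c`, `P(w > c) P(b <= c) <= P(w > b)`, with
near-equality only when the sets are nearly separated.  For strongly
overlapping sets every verified product therefore sits strictly below H+
and the window intersection is *empty at any p*; the function then warns
and returns an empty list rather than widening the window.  The
factorisation is informative exactly when clusters are close to concordant
(H+ near 0 — i.e. 1 - H+ near 1 — or sets nearly disjoint), which is the
regime where one wants to quote statements like "all within distances are
below 95% of between distances".

## Bootstrap estimation (HPB)

Each of `r` replicates draws `t_j` observations with replacement from
cluster `j`, where `t_j` is the largest-remainder rounding of `b_j * t`
with a floor of one draw per cluster (remainder ties go to the larger
cluster, then the earlier index), so `sum t_j = t` exactly and no cluster is
starved.  The replicate's `t x t` dissimilarity matrix is computed from raw
data (any of the five supported metrics) or sub-indexed from a precomputed
matrix, exact H+ is evaluated on it, and the `r` values are averaged.
Per-replicate H+ is exact rather than sketched: at the default `t = 100`
a replicate holds only 4950 distances, so exactness costs nothing.
Duplicated observations contribute zero within-distances; this is a
faithful bootstrap draw and is kept.  A replicate with an empty within or
between set (possible only when `t` is as small as `k`) is redrawn at most
10 times, then an error is raised.

Defaults follow the recommendation `r = 0.05 n` (floored at 30 for small
data) and `t = 100`.  The result reports the replicate mean `H_b`, the
replicate standard deviation, and the full estimates vector; the standard
error of `H_b` is `sd / sqrt(r)`.  Everything is reproducible under a fixed
seed (PCG64).

## Simulation designs

`gaussian_mixture` draws `n` observations with `f` independent features
from `b * N(mu_x, sigma^2) + (1-b) * N(mu_y, sigma^2)`, with the mean
difference `delta = mu_x - mu_y` applied identically to every feature and
*deterministic* group sizes `round(b n)` / `n - round(b n)` (not Bernoulli
assignment), so `alpha` is exactly reproducible across seeds.  Defaults
used throughout the tests and the acceptance script are the reference study
conditions: `n = 1000`, `f = 500`, `sigma = 1`, `delta = 0` for the null,
`b in {0.5, 0.9}` for the balance contrast.  Under the null every pairwise
distance has the same distribution, so the true `P(w > b)` is exactly 1/2
regardless of balance — the property the balance sweep demonstrates.

`gaussian_distance_sets` skips the data-matrix stage and draws the distance
sets themselves from two normals, giving a closed-form truth
`P(W > B) = Phi((mu_w - mu_b) / (sigma sqrt 2))` that serves as an analytic
oracle (the canonical demo: `N(0.3, 1)` vs `N(-0.3, 1)`, truth 0.664).

What the generators do *not* emulate: real expression data are counts with
mean-variance dependence, correlated features, and non-Gaussian distance
distributions.  Passing tests establish the metric's distributional
properties (unbiasedness, balance invariance, estimator accuracy), not
performance claims about any particular real data set; the distance-level
machinery is distribution-free, so the estimator guarantees (1/p bound,
bootstrap consistency) carry over unchanged.

## Evaluation module

ARI (pair-counting form) and mean silhouette (`(b - a)/max(a, b)`,
singletons scored 0) are implemented directly — they are small, standard
formulas and keeping them internal avoids a runtime dependency — and are
cross-checked against scikit-learn in the test suite.  WCSS is computed
from the dissimilarity matrix via the centroid identity
`sum_i ||x_i - c_j||^2 = (1/n_j) sum_{i<i'} d_{ii'}^2`, exact for Euclidean
input and a dispersion analogue otherwise.  `k_sweep_report` tabulates
`1 - H+`, silhouette, WCSS and (optionally) ARI across candidate
labellings; degenerate candidates yield NaN plus an error note instead of
aborting the sweep.  On synthetic three-group data with candidates built by
merging/splitting the true groups, `1 - H+` peaks at the true `k = 3`.

## Command-line interface

The `hplus` console script wires the modules together; results are JSON/CSV
on stdout, logs on stderr, and every record echoes the package version and
configuration.  Exit codes: 0 success, 1 degenerate partition, 2 input
error.  A JSON `--config` file supplies per-subcommand defaults; explicitly
passed flags always take precedence (defaults-then-flags is the only
ordering consistent with shell conventions).  Dense matrices are CSV/TSV
value grids; condensed vectors are one value per line in row-major `i < j`
order; labels are one string per line; sparse count matrices use
MatrixMarket.  The five supported dissimilarities are Euclidean, Maximum
(Chebyshev), Manhattan, Canberra (zero-denominator terms skipped), and
Binary (Jaccard on nonzero indicators; all-zero pairs are 0 with a
warning).  `log2(x + 1)` normalisation and a top-variance feature filter
are provided as explicit opt-in transforms, never applied implicitly.

## Problem sizes in the test and acceptance runs

Null-mixture checks use `n = 1000`, `f = 500` over 10 seeds (5 replicates
per balance in the sweep); the distance-set example uses 10,000 draws per
set; the bootstrap-vs-sketch comparison uses `n = 3000`, `f = 100`,
`delta = 0.3`, `r = 150`, `t = 100` against the `p = 10001` sketch, with
the median discrepancy over seeds reported.  These sizes keep the full
suite to a few CPU-minutes while leaving Monte-Carlo error well inside the
tolerances quoted in the tests.

## Known limitations

* Strict-inequality counting makes H+ conservative on heavily tied inputs;
  inspect the reported tie count before interpreting near-zero values.
* The gamma factorisation is uninformative (empty) for strongly
  overlapping distance sets, as discussed above.
* The sketch guarantee degrades when `p` approaches the distance-set sizes;
  the package does not forbid such calls, it documents them.
* No permutation or significance testing is provided; H+ is a descriptive
  fitness estimate, not a test statistic.
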