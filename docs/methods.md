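# Methods

## Null model

For gene *j* in cell *i* the raw UMI count is modeled, under the null
hypothesis of a homogeneous cell population, as a Poisson sample of a
lognormal biological rate:

    x_ij ~ Poisson(LogNormal(mu_ij, c))

The lognormal is parametrized by its **actual** mean and coefficient of
variation — not by the location/scale of the underlying normal. This is the
single most error-prone convention in the package; the conversion used
everywhere is `s^2 = ln(1 + c^2)`, `location = ln(mean) - s^2/2`, and it has
dedicated unit tests. The null expectation `mu_ij = d_i m_j / T` (cell depth
x gene total / grand total) preserves all matrix margins exactly and absorbs
sequencing-depth variation, so no count normalization is ever applied.

Two facts make the modified corrected Fano factor

    phi'_j = 1/(n-1) * sum_i (x_ij - mu_ij)^2 / (mu_ij (1 + c^2 mu_ij))

a calibrated statistic: the denominator `mu (1 + c^2 mu)` is exactly the
Poisson-lognormal variance, so `E[phi'] ~ 1` at every expression level and
depth profile; and the full null distribution of `phi'` is accessible
through its moments, because per-cell moments of the squared residual follow
from Poisson-lognormal moments and cumulants add across independent cells.

## Moments without cancellation

Raw lognormal moments are `E[Y^k] = mu^k beta^(k(k-1)/2)` with
`beta = 1 + c^2`; factorial moments of the Poisson-lognormal equal raw
lognormal moments, giving raw count moments through the Stirling-number
transform. Central moments up to order 10 are needed for five moments of
the squared residual, and forming them from raw moments in floating point
loses up to ten significant digits to cancellation. Instead, each central
moment `E[(X - mu)^r]` is assembled once per `c` as a degree-`r` polynomial
in `mu` whose coefficients are computed in exact rational arithmetic
(`fractions.Fraction`), combining integer-coefficient Poisson central-moment
polynomials (from the recurrence `m_{r+1} = lambda (dm_r/dlambda +
r m_{r-1})`) with exact finite differences of lognormal moments. The float
conversion happens only at the final coefficients; polynomial evaluation is
vectorized over cells in gene chunks, so the cost is O(cells x genes)
elementary operations and no dense intermediate larger than one chunk.
The assembly was verified against an independent all-rational route to
machine precision at order 10.

## Accounting for estimated means

Observed `phi'` uses `mu_ij` estimated from the data's own margins. This is
not a small correction: the sum of squared deviations and the variance
denominator move together with the estimated gene mean, which cancels a
large part of the statistic's fluctuation (about 45% of the variance at
`c = 0.7`, 2,000 cells). Treating `mu_ij` as fixed therefore overpredicts
the null spread and makes p-values conservative by roughly a factor two at
the 0.05 level. The package linearizes `phi'` in the estimated per-gene
rate (a first-order von Mises expansion): each cell's contribution becomes
`Q_i - a (x_i - mu_i)` with the gene-level coefficient

    a = [ sum_i (1 + 2 c^2 mu_ij) / (1 + c^2 mu_ij) ] / [ sum_i mu_ij ],

which for equal cells reduces to the derivative `1 + 2 c^2 mu` of the
variance function. Cumulants of the adjusted per-cell variable need joint
central moments of orders up to 10, all available from the same polynomial
tables. Monte-Carlo oracles in which the mean is re-estimated per draw
confirm the adjusted second cumulant to within MC error and place the
predicted tail probability at the empirical 95th percentile between 0.039
and 0.059 across 20 (mean, c, depth-profile) configurations at 300 cells.
`fano_null_moments` exposes both variants (`mean_adjusted=`); the selection
pipeline always uses the adjusted one.

## Tail probabilities

The upper-tail probability of an observed `phi'` is obtained by inverting
the Cornish-Fisher quantile polynomial built from the five null cumulants,
then mapping the matched normal quantile through the Gaussian survival
function. Two guards protect the inversion. First, a convergence check: the
expansion is asymptotic, and the fifth-cumulant term is used only when its
contribution at the working part of the upper tail (z ~ 2) is small against
the lower-order corrections — when the fifth standardized cumulant is large
(small cell counts, weak expression), adding its term overshoots the tail
and the four-moment expansion is strictly more accurate. Second,
monotonicity: the quartic quantile polynomial is not globally monotone;
since the test is one-sided, the guard requires only that the
monotone-increasing branch containing the far upper tail (standardized z up
to 40) extends down to z = -1. Below that branch the observation is deep in the lower tail and
p is reported as the survival value at the branch edge (close to 1), which
is the intended behavior for under-dispersed genes. If the guard fails, the
expansion degrades to the four-moment version and finally to a plain
Gaussian tail, with the downgrades logged. P-values are clamped to
[1e-300, 1] for representability. Against an exact chi-square oracle (mean
of 50 chi-square(1) variables) the five-cumulant tail is accurate to 0.02%
at p ~ 0.013.

## Fitting the consensus c

`c` is assumed shared across genes and most genes are assumed
non-differential. Because `c` barely moves `phi'` when `mu_ij << 1`, lowly
expressed genes anchor the statistic and a wrong `c` tilts `log10 phi'`
against `log10 mu`: too-small `c` tilts it upward, too-large downward. The
fit minimizes the absolute OLS slope over genes with mean in [0.01, 10]
(constant genes excluded from the log fit), seeding a bounded Brent search
on c in [0, 3] (absolute tolerance 1e-3) with a 31-point grid. On null
simulations the generating c in {0, 0.25, 0.5, 0.7, 1.0} is recovered with
mean absolute error well under 0.1. On datasets where many genes are truly
variable the fitted c is biased upward, since variable genes inflate the
high-expression end of the trend; the fit is best run on data expected to
be mostly homogeneous.

## Selection policy

Significance and magnitude are separate axes: a gene must have
`fdr < 0.05` (Benjamini-Hochberg over all tested genes) and `phi'` at or
above a quantile of the **significant** genes' values. Boundary ties are
included, so quantile 0 keeps every significant gene. Recommended defaults
derive from dataset statistics: fewer than 150 cells or median depth below
3,000 UMI/cell keeps the top 10%; large deep datasets with under 5% of
genes significant keep the top 1%; otherwise the top 10%. An FDR threshold
of 1 disables significance entirely, for exploratory phi'-only ranking.
Genes detected in at least `min_cells = 3` cells are tested; genes with
mean below 0.01 are reported but flagged `low_expression` rather than
dropped, since their phi' is numerically delicate.

## Synthetic data generator

The generator reproduces the benchmark study conditions and doubles as the
test bed: gene means log-uniform on 10^(-1)..10^(0.8) (about 0.1 to 6.3 UMI
per cell), biological CV `c = 0.7`, 2,000 cells in two equal groups, 15,000
genes of which a configurable subset is "truly variable" (independent mean
draws per group, so between-group differences are centered on zero).
Sequencing depth is constant by default and can be varied through per-cell
multiplicative factors on the lognormal mean (log-uniform over a chosen
fold range, normalized to mean 1). Random streams are split per gene, so
changing the number of variable genes leaves all other genes' counts
bit-identical under the same seed. Rare-cell tasks are built by
downsampling one labeled population to a fixed fraction (default 5%,
i.e. 1:19) of the mixture and removing genes detected in fewer than three
cells.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene-gene correlation, zero inflation beyond the
Poisson-lognormal, or empirical depth distributions. Passing tests
demonstrate internal statistical correctness under the model, not
robustness to those artifacts in real tissue data.

## Evaluation statistics

Clustering quality against known target cells uses the purity score (the
fraction of target cells captured by the cluster holding most of them) with
an upper-tail hypergeometric p-value `P(K >= k)` for observing that
concentration under random placement — a tail rather than a point mass,
since it is used as a p-value. Ties between clusters with equal target
counts go to the smaller cluster (higher concentration) and are flagged.
Normalized entropy divides the Shannon entropy of the targets' distribution
over clusters by `ln(n_clusters)`. Enrichment scores divide a marker's mean
log-normalized expression in a cluster by its dataset-wide mean (raw means
are available by passing a raw matrix). The clustering adapter is
deliberately thin — log-normalize (`ln(count/total x 1e4 + 1)`), subset to
features, up to 50 principal components, k-nearest-neighbor graph, Leiden
at a given resolution and seed — and is deterministic for fixed inputs; its
internals carry no methodological content. The multi-seed protocol reports
median and IQR across (by default) 40 Leiden seeds.

## Problem sizes and numerical choices in the tests

Session-level simulations: 2,000 x 2,000 null (centering, uniformity),
2,000 x 5,000 null (CV recovery), 2,000 x 15,000 with 1,000 variable genes
(FDR control, selection precision, end-to-end clustering over 10 seeds at
resolution 0.1). The Monte-Carlo tail-oracle suite uses 300 cells and 1e5
draws per configuration. Moment identities are checked at 4e5-1e6 draws
with batched standard errors (3 SE criteria). All stochastic tests are
seeded and deterministic.

## Known limitations

- The tail expansion is asymptotic in cell count: at a few hundred cells,
  p-values of weakly expressed genes (`mu` below ~0.2) are mildly
  conservative (predicted tail ~0.04 at the true 0.05 point at 300 cells),
  and the gap widens as cells get fewer. This errs against false positives.
- The estimation adjustment is first order; second-order terms shift the
  null mean by O(1/n), negligible at hundreds of cells but untested below
  ~50 cells.
- A single consensus `c` is used; per-gene `c_j` is accepted by the data
  model but not estimated.
- `phi'` of genes expressed in very few cells is dominated by a handful of
  observations; the `low_expression` flag marks where the asymptotics are
  least trustworthy.
- The clustering adapter inherits any nondeterminism of its backends across
  library versions; determinism is guaranteed only within one environment.
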