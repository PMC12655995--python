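# Methods

`cacaopheno` implements the statistical pipeline used to characterize and
structure a clonal cacao (*Theobroma cacao* L.) germplasm collection from
replicated agromorphological trial data, and to select promising accessions
for breeding.  This note documents the models, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions that were genuinely open.

## Trial model and genetic parameters

The observational unit is one descriptor measured on one graft of one
accession in one season.  For a quantitative descriptor the working model is
the randomized clonal-trial decomposition

    y_ij = mu + g_i + r_j + e_ij

with accession (genotype) effects `g_i`, replication effects `r_j` (each
season x graft combination is one replication; the two evaluation seasons
are pooled into the replication stratum rather than modelled as a main
effect, because the collection is characterized on pooled two-season data),
and residuals `e_ij`.  Variance components come from the genotype x
replication mean squares via the expected-mean-squares identity

    GV = (MSG - MSE) / r,    EV = MSE,    PV = GV + EV

with `r` the effective replication (harmonic mean of per-accession
observation counts under unbalance; sequential sums of squares with
replication fitted before genotype).  Negative method-of-moments GV is
truncated at zero so that heritability and GCV stay real-valued.

Derived parameters, all on the conventional scales:

* `GCV = 100 * sqrt(GV) / mean`, `PCV = 100 * sqrt(PV) / mean` (%)
* broad-sense heritability `H2 = 100 * GV / PV` (%)
* genetic advance `GA = k * sqrt(PV) * GV / PV` (trait units) and
  `GAM = 100 * GA / mean` (%)

The selection differential defaults to `k = 2.06` (5% selection intensity).
This value reproduces the published genetic-advance column of the reference
collection to within printing precision (verified on the fruit-mass,
pericarp-mass and seed-mass rows before being fixed as the default); it
remains a configurable argument.  Classification bands follow the standard
convention: GCV/PCV and GAM low < 10, moderate 10–20, high > 20; H² low
< 30, moderate 30–60, high > 60 (all %).

Repeatability across seasons is the one-way intraclass correlation of
accession season-means, `r = (MSB - MSW) / (MSB + (m - 1) MSW)` with `m`
the (harmonic-mean) seasons per accession; values above 0.40 are labelled
moderate-to-high.  In clonal material this is an upper bound on
broad-sense heritability.

## Outlier screening

Grubbs' two-sided test is applied iteratively (most extreme point first)
per descriptor on accession-level means at alpha = 0.05, using the t-based
critical value `((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))` with the upper
`alpha/(2n)` t quantile on `n - 2` df.  Screening accession means (rather
than raw observations) targets implausible genotypic values; replicate-level
noise is already absorbed by the variance decomposition.  Removal stops when
no point is rejected or when only three points would remain, so at most
`n - 3` points are ever removed.

## Multivariate structuring

Clustering operates on the accession x descriptor matrix of means,
mean-imputed and standardized (mean 0, SD 1).  PCA is performed on the
correlation matrix; eigenvalues sum to the number of variables, the
contribution of variable *j* to dimension *k* is `100 * v_jk^2`, and the
retained dimension count is the smallest that includes every eigenvalue > 1
and reaches 75% cumulative variance.

Hierarchical clustering uses Euclidean distance with Ward's minimum-variance
criterion in its D2 form (squared-distance Lance–Williams update, heights on
the distance scale); the D1 variant is deliberately not offered.  K is
selected by the average-silhouette argmax over k = 2..12 on the original
Euclidean distances (not tree heights), with the Tibshirani gap statistic
(uniform-box reference sets, `gap(k) >= gap(k+1) - se(k+1)` rule) computed
alongside as a cross-check; both curves are always reported, and a fixed K
override is available because K choice in germplasm studies often mixes
statistics with judgment.

Node stability uses multiscale bootstrap resampling of *descriptors*
(columns) — the clustered objects are accessions, so perturbing the
descriptor set asks whether the grouping survives a different choice of
traits.  Scales default to 0.5–1.4 in 0.1 steps with replicates split
evenly.  For each internal node the per-scale bootstrap proportion `BP_r`
is mapped to `z_r = qnorm(1 - BP_r)` and the signed-distance model
`z(r) = d sqrt(r) + c / sqrt(r)` is fitted by weighted least squares
(binomial-variance weights); the approximately unbiased support is
`AU = 1 - Phi(d - c)`.  Scales where BP is saturated at exactly 0 or 1
carry no curvature information and are excluded from the fit; if fewer than
two informative scales remain the AU degrades to the plain BP (a node never
recovered at any scale is reported AU = 0 with an `unseen` flag).

The cluster-distance summary is a K x K matrix whose diagonal holds the
mean within-cluster pairwise Euclidean distance and whose off-diagonal
holds mean between-cluster pairwise distances; each cluster's mean distance
is the average of its K-1 inter-cluster entries.  Singleton clusters have
no within-distance and are reported as 0 with a flag.

## Per-cluster inference

With phenotypic clusters fixed, each descriptor is compared across clusters
by the fixed-effects one-way model `Y_ij = mu + alpha_i + e_ij`, with each
accession's mean treated as one replicate of its cluster (unbalanced
layout).  Normality of residuals is checked by a Kolmogorov–Smirnov test
with Lilliefors correction — parameters are estimated from the data, so the
plain KS p-value would be anti-conservative; the null distribution of the
statistic is simulated (10^4 Monte-Carlo replicates, seeded).  Variance
homogeneity uses Bartlett's test.  Pairwise comparisons use the
Tukey–Kramer studentized-range procedure with the unbalanced-size standard
error, summarized as a compact letter display built by insert-and-absorb
followed by a pruning pass that removes any letter whose deletion leaves
the sharing <=> non-significance equivalence (and full coverage) intact, so
the display is minimal.  Letters are assigned from the largest mean
downward.  No multiplicity correction is applied across descriptors; each
descriptor is reported marginally and this is recorded in the output
metadata.

## Bayesian bivariate selection

The two yield-discriminant descriptors are the seed index SI (mean dry
single-seed mass, g; higher is better) and the pod index PI (pods per kg of
dry seed; lower is better).  Accession x season means enter the bivariate
mixed model

    y_is = mu + a_i + e_is,  a_i ~ N2(0, Sigma_a),  e_is ~ N2(0, Sigma_e)

fitted by a Gibbs sampler with conjugate updates (Gaussian for `mu` and the
`a_i`, inverse-Wishart for both covariances).  The prior is
inverse-Wishart(nu = 3, scale = 0.01 I) on both covariances — a
weakly-informative default standing in for "non-informative"; it is
configurable and the posterior is insensitive to it at the fitted data
sizes.  A single chain is run with ESS and Geweke z diagnostics (|z| > 3 on
a variance parameter flags non-convergence in the output; it is never
silent).  Default chain: 1000 burn-in + 5000 iterations thinned by 2.

The Bayesian Yield Stability Index is computed on posterior *genotypic*
values `mu + a_i` (stability of the genotype is the selection goal, so the
posterior-predictive alternative is not used): for SI it is the 10th
posterior percentile (the value exceeded with 90% probability), and for PI
— where lower is better and the convention had to be chosen — the mirrored
90th percentile (the value not exceeded with 90% probability).  95% HPD
intervals of the genotypic values accompany the index.  An accession is
promising iff `BYSI_SI > 0.8 g` and `BYSI_PI < 23.5`; thresholds apply to
the BYSI values by default (a raw-means mode exists), and the selected
fraction is reported as a percentage of all accessions.

## Phytochemical module

Instrument responses are converted to concentrations by inverting linear
calibration curves, `x = (y - b)/m` (Trolox equivalents for DPPH, gallic
acid equivalents for total phenolics); negative inversions are flagged as
below-range, never silently clipped.  The theobromine/caffeine ratio
assigns the classical genetic groups: Criollo < 2, Trinitario in the
*closed* interval [2, 9], Forastero > 9 — the closed middle band is the
only assignment consistent with strict outer bounds.  The correlation
network correlates accession-level triplicate means; an edge is kept iff
`|r| >= r_min` (default 0.7) and `p < alpha`, and constant variables are
excluded with a flag.

## Synthetic generator

The generator is the pipeline's test bed and defines its study conditions:
113 accessions, 6 measured grafts per accession (nine are planted in the
emulated design; the measured subset per season is not knowable, so six was
fixed once as realistic), two seasons (2023/2024), eight planted phenotypic
clusters, and per-trait means and variance components set to the published
estimates of the reference collection (the few descriptors whose published
PV equals GV at printing precision get an EV floor of 0.1% of GV so
replicate noise stays positive).

For trait *t*, accession *i*, observation *(j, s)*:

    y = mu_t + c_{k(i),t} + g_{i,t} + e_{ijs,t}

Cluster structure is placed on genotypic values (not residuals).  The
`separation` knob splits GV between the centroid and deviation layers with
between-cluster share `s^2 / (1 + s^2)`, so the centroid spread is `s`
times the within-cluster genotypic SD.  Drawn centroids are size-weighted
standardized so the realized between-cluster variance equals its target
exactly — with only K centroid draws the realized variance would otherwise
be far from nominal and planted GV would be unrecoverable even in large
trials.  Accession deviations are jointly Gaussian across traits via the
symmetric PSD square root of the target genotypic correlation matrix
(defaults plant the strong fruit/seed correlations typical of cacao:
fruit mass–pericarp mass 0.95, seed-count correlations 0.87–0.93).
Residuals are iid Gaussian.  Season effects default to zero (pooled-season
model); an additive shift is available for repeatability experiments.
Qualitative descriptors are accession-level attributes drawn from
cluster-specific level frequencies (Dirichlet-drawn per cluster).
Everything is a deterministic function of one seed.

What the generator does **not** emulate: spatial field autocorrelation,
genotype x season interaction beyond additive shifts, pollination/xenia
effects on seed traits, non-Gaussian trait distributions, and missingness
mechanisms (cells are complete unless removed).  Passing tests therefore
demonstrate correctness of the estimators and algorithms under the assumed
model, not robustness to these real-data features.

The phytochemical generator mirrors cotyledon panels: triplicate assays,
between-accession spread per assay, a planted theobromine–total-phenolics
correlation of 0.95 (with the implied negative correlations to the CIELAB
b* coordinate), and a random ~47% of accessions with no detectable
catechin.

## Numerical choices and problem sizes

* Ward linkage ties resolve to the smallest index pair; duplicate points
  merge at height zero.
* Gap statistic reference sets: uniform boxes over the per-column ranges of
  the standardized data, 50 references by default.
* Lilliefors Monte-Carlo p-values use `(hits + 1) / (sims + 1)`.
* The studentized-range CDF comes from scipy's numerical integration; for
  extreme q values `sf` underflows to 0, which is the correct selection
  decision at any alpha.
* Simulation-based checks use 200 seeds for variance-component and
  repeatability recovery, 50 seeded runs at 5000 Gibbs iterations for
  interval coverage, 1000 replicates for the Grubbs type-I rate, and 10^6
  draws for the BYSI closed-form comparison; these sizes put Monte-Carlo
  error well inside the asserted tolerances while keeping the default suite
  quick.
* `RunConfig` expands one global seed into fixed per-stage offsets so
  toggling one pipeline stage never shifts another stage's random stream.

## Known limitations

* The variance decomposition assumes additive replication effects; strong
  genotype x replication interaction inflates EV and biases GV downward.
* AU support is estimated from finite bootstrap counts; with small B per
  scale the weighted fit is noisy for nodes with intermediate BP.
* The Gibbs sampler covers exactly two traits; more traits or spatial
  adjustment are out of scope.
* Published-table consistency checks are limited by the two-decimal
  printing of their inputs: quantities derived from small printed variances
  (e.g. GV = 0.01) are only reproducible to the propagated rounding
  interval, not to +-0.05.
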