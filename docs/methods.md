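# Methods

This note records the statistical models implemented in `mucolink`, the
numerical choices behind them, what the synthetic cohort generator does and
does not emulate, and the design decisions taken where more than one
reasonable implementation existed.

## Compositional analysis and the dysbiosis score

Taxon count tables are treated as compositions. The centered log-ratio (CLR)
transform maps each sample to `log(x + pc) - mean(log(x + pc))`; Euclidean
distance between CLR rows is the Aitchison distance, and alpha diversity is
the Shannon index on relative abundances.

*Zero handling.* A uniform additive pseudocount (default 0.5 counts) is
applied before taking logs. This is the simplest documented strategy; it is
exposed as a parameter so multiplicative replacement can be emulated
upstream if desired. `pseudocount=0` is allowed only for strictly positive
matrices, where CLR scale invariance holds exactly.

*Dysbiosis score.* Each sample's score is the **median Aitchison distance to
the reference (non-IBD control) samples**. A control is scored leave-self-out
(median over the other controls) so its guaranteed zero self-distance cannot
deflate its score. The classification threshold is the empirical quantile
(default 0.9, linear-interpolation definition) of the score vector over all
scored samples; a sample is dysbiotic iff its score is *strictly greater*
than the threshold. The quantile is computed over all scored samples by
default; computing it within diagnosis strata is left to the caller by
scoring strata separately.

*PERMANOVA.* Anderson's pseudo-F from among/within sums of squared
distances, with `p = (1 + #{F_perm >= F_obs}) / (B + 1)`, so p can never fall
below the permutation resolution. Labels permute freely by default; a
`strata` argument restricts permutation to within-stratum exchanges (e.g.
within patients) when repeated measures make free exchange inappropriate.

## Random-intercept linear mixed models

Every association model is a Gaussian LMM with one random intercept per
patient, `y = X b + Z u + e`, estimated by REML. The models are Gaussian with
identity link throughout because all responses (log expression, CLR
abundance, enrichment scores) are continuous.

*Estimation.* Profiling the likelihood over `gamma = sigma2_u / sigma2_e`
reduces the problem to one dimension. The eigendecomposition of the patient
incidence structure `Z Z'` is computed once per grouping and shared across
the thousands of per-pair fits in a scan; each REML evaluation is then a
weighted least-squares solve with weights `1/(1 + gamma * s_i)`. The
criterion is minimized by golden-section search over `log gamma` in
[-12, 12] with tolerance 1e-8, and the exact `gamma = 0` (OLS) boundary is
always evaluated as a candidate; when every patient contributes one biopsy
the variance ratio is unidentifiable and the fit returns the boundary.

*Inference.* Wald t statistics with `df = n - rank(X)`. Satterthwaite-type
df corrections are not implemented; at the cohort sizes targeted here
(hundreds of biopsies) the difference is negligible, and the null
calibration of the scans is verified empirically in the test suite. Designs
are validated by pivoted QR; rank-deficient designs are rejected with the
aliased columns named. Categorical covariates are treatment-coded against
the first sorted level, so encodings do not depend on row order.

*Scans.* The association scan fits `gene ~ taxon_CLR + covariates + (1|patient)`
per pair and reports the taxon slope. The interaction scan adds dysbiosis
status and its product with the taxon term; the eubiotic slope is the taxon
main effect, the dysbiotic slope is main effect + interaction. Taxon
abundance enters on the CLR scale by default. Benjamini-Hochberg adjustment
is applied jointly across all pairs of one scan invocation. The permutation
false-positive estimate reruns the interaction scan with dysbiosis labels
shuffled across samples (the dysbiotic count is preserved by construction)
and reports the mean BH-significant count divided by the number of pairs.

*Wilcoxon tests.* Rank-sum and signed-rank tests use the exact null
distribution for samples of at most 25 without ties and the tie-corrected
normal approximation otherwise.

## Sparse canonical correlation (penalized matrix decomposition)

Given residualized, column-standardized taxa (X) and gene (Y) matrices, each
component solves `max u' K v` with `K = X'Y/(n-1)`, `||u||2, ||v||2 <= 1`,
`||u||1 <= c1`, `||v||1 <= c2`, by alternating soft-threshold updates; the
threshold is found by bisection as the smallest value meeting the L1 bound.
Components are extracted with rank-1 deflation `K <- K - d u v'`. The
penalty scale is `c = max(1, lambda * sqrt(p))` per side, so `lambda = 1`
leaves a side unconstrained. Residualization removes the confounders and the
predicted patient intercepts (conditional residuals) before the
decomposition; constant columns are dropped with a warning, never imputed.

*Convergence.* The alternation stops when the v update moves less than the
tolerance, or — once thresholding is active — when the objective `u'Kv` has
stalled: with active L1 bounds and near-degenerate singular values the
iterate can rotate indefinitely inside an invariant subspace at constant
objective, and any vector in that subspace is an equally good solution. The
unpenalized path is plain power iteration and always runs to the v
criterion, which is what the SVD-equivalence tests rely on.

*Module membership.* The L1 bound is a ratio constraint; solutions ride the
boundary with a tail of numerically tiny loadings (observed: planted
loadings around 0.22 against a tail below 0.05). `CcaComponent.members()`
therefore defines membership as loadings of at least 10% of the side's
largest absolute loading. The raw loading vectors, which satisfy the L1/L2
constraints exactly, are always retained.

*Penalty tuning.* Grid search (default lambda in {0.05, ..., 0.50} on both
sides) by k-fold cross-validation on the held-out score correlation of the
first component; ties prefer the sparser pair.

*Component significance.* Components are scored by **held-out canonical
score correlation**: the model is refitted with each CV fold left out
(default 5 folds), loadings are sign-aligned to the full-data fit, and the
held-out score pairs of each fold are correlated using directions estimated
strictly outside that fold. Fold-wise Fisher z statistics are averaged and
referred to a standard normal — an upper bound on the variance of the mean
regardless of between-fold dependence, hence a valid (conservative) p-value
— then BH-adjusted over components with keep threshold adjusted P < 0.1.
A per-left-out-sample (leave-one-out) version of this statistic was
implemented first and rejected: the n held-out score products share one
estimated direction, so their sum tracks the in-sample canonical correlation
and the resulting test is badly anticonservative on independent noise. The
fold-held-out form restores calibration (verified on null cohorts in the
test suite) at a modest cost in resolution.

*Annotation.* Gene-set over-representation of module members is one-sided
hypergeometric against a caller-supplied background with BH adjustment;
gene sets load from GMT files.

## Association networks and the per-taxon shift test

Networks are bipartite: one edge per BH-significant (taxon, gene) pair,
signed by the slope and weighted by `|Z| = |beta/se|` so genes on different
scales are comparable. Reporting follows the largest-connected-component
convention (ties resolve to the lexicographically smallest node set), with
degree and Brandes betweenness on the unweighted LCC, plus each taxon's
share of all edges.

The shift test asks, per taxon, whether its associated genes rank
differently between two phenotype groups. All background genes are ranked by
Z within each group — ranking over the full background makes the comparison
invariant to group-level differences in Z scale — and the two rank lists are
compared over the union of genes BH-significant for that taxon in either
group, with a paired Wilcoxon signed-rank test (an unpaired rank-sum variant
and an all-genes scope are available behind flags). Taxa with fewer than 3
comparable genes are skipped and logged; p-values are BH-adjusted across
tested taxa.

## Lasso variance partitioning

Six designs are fitted per cell type: basic (age, sex, BMI, batch),
medication flags, inflammation, tissue location, all CLR taxa, and the full
concatenation. The solver is cyclic coordinate descent with soft
thresholding on standardized predictors (covariance updates with an
active-set strategy; convergence when the largest coefficient change falls
below 1e-7; KKT conditions are verifiable for every fit). The penalty path
is 100 log-spaced values from `lambda_max` down to `0.001 lambda_max`;
10-fold CV with seeded fold assignment picks `lambda_min`. The headline
statistic is cross-validated `R^2 = 1 - CV_MSE/Var(y)` rather than in-sample
R^2; negative values are floored at 0 for reporting with the raw value
retained. For the bacteria model, per-taxon contributions are standardized
|beta| shares, which are nonnegative and sum to 1.

## The synthetic cohort generator

The generator emulates a mucosal biopsy cohort with repeated measures:
each patient contributes several biopsies; covariates follow
age ~ U(18, 80), BMI ~ N(25, 4), sex/inflammation/location/medication flags
~ Bernoulli, batch ~ categorical(4); covariate effects are random per-feature
coefficients on the log/CLR scale. Taxon counts arise as latent Gaussians ->
softmax composition -> multinomial draws at Poisson library sizes (mean
20,000 reads). Gene expression is emitted directly on the log scale, since
every downstream analysis acts on normalized values.

Planted structure and the reasoning behind the defaults:

- **Modules.** Latent factors shared by a block of taxa (loading 1) and a
  block of genes (loading `module_strength`, default 0.8). Planted-module,
  interaction and hub taxa draw moderately common baselines (N(1, 1) against
  N(0, 2) for the rest): detectable host-microbe modules involve prevalent
  genera, and the CLR values of rare, dropout-ridden taxa are mostly noise.
- **Structural zeros.** Dropout probability falls logistically with latent
  abundance (offset solved so the marginal rate equals `zero_inflation`,
  default 0.1 structural dropout on top of multinomial sampling zeros), so
  prevalent taxa are essentially never zeroed — as in real 16S data, where
  prevalence tracks abundance. Uniform random dropout was tried first and
  rejected: the pseudocount floor then dominates CLR variance for every
  taxon and buries all planted structure.
- **Dysbiosis.** A fraction of non-control samples (default 0.1) is
  displaced by a fixed vector of norm `dysbiosis_shift` (default 14) in
  latent space, spanning the *non-planted* taxa: planted taxa participate
  through their gene associations, not as drivers of the community shift —
  a displacement concentrated on a planted taxon pushes it below detection
  in dysbiotic samples and destroys the within-stratum variation the
  interaction models need. The default magnitude separates the
  median-distance score of dysbiotic samples by several score standard
  deviations, as expected for a clearly disturbed community.
- **Interaction pairs** add `+slope * z` (eubiotic) / `-slope * z`
  (dysbiotic) to a gene, where z is the taxon's standardized *pre-shift*
  latent: planting on the post-shift latent would let the common
  displacement leak into the genes and couple them to every taxon.
- **Group edges** add slope `+c` to selected genes in one phenotype group
  and (flip mode, default) `-c` in the other, concentrated on one hub taxon
  per group.
- **Cell scores** are weighted sums of a few taxa's CLR values plus noise
  scaled to a target generating R^2 (default 0.5 from 5 taxa).

What the generator does **not** emulate: phylogenetic correlation among
taxa, realistic taxon/gene names, overdispersed (beyond multinomial +
lognormal-latent) counts, longitudinal dynamics, missing metadata, and
technical batch effects beyond additive shifts. Passing recovery tests on
these cohorts therefore demonstrates correctness of the statistical
machinery under the planted generative model, not performance guarantees on
real mucosal data, where effect sizes are smaller and confounding richer.

## Pipeline

The pipeline wires the stages end to end: load/align -> CLR, diversity,
distances, dysbiosis -> residualize -> sparse CCA per inflammation stratum
with CV significance -> association scan -> phenotype networks and shift
tests -> interaction scan with permutation false-positive estimate ->
variance partitioning. Configuration is TOML; all randomness derives from a
single root seed through fixed per-stage offsets, making outputs
byte-identical across runs. Samples missing from any input table or with
missing modeled covariates are dropped with logged counts; imputation is out
of scope.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on cohorts of 100-330
biopsies (50-165 patients, two biopsies each), 10-300 genes and 5-50 taxa,
with 5-40 generator seeds per property. These sizes were chosen so planted
effects sit in the moderate-power regime — large enough that recovery
separates cleanly from the null behavior being verified, small enough that
every check derives from freshly generated data at run time.

## Known limitations

- Wald t inference without small-sample df correction.
- The dysbiosis quantile is computed over all scored samples; stratified
  thresholds require scoring strata separately.
- The CV component-significance p-value is conservative by construction;
  marginal components near the threshold may be under-kept.
- Lasso contribution shares describe the fitted sparse model, not a causal
  decomposition; correlated taxa share credit arbitrarily.
- PERMANOVA assumes exchangeability under the chosen permutation scheme;
  with repeated measures use the strata argument.
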