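# Methods

monekit treats the channels of a CNN's global-average-pooling layer —
"mones", morphological genes — the way expression analysis treats genes: a
slide is a sample, a mone is a variable, and the toolbox is differential
statistics, correlation networks, linear classifiers and cross-modality
correlation. This note records the models, the conventions the
implementation fixes where several are defensible, and what the synthetic
benchmarks do and do not establish.

## Slide-level aggregation

Tile-level feature vectors are collapsed to one row per slide by the
per-feature **median** over the slide's tiles. The median of an even tile
count is the mean of the two central order statistics (the standard sample
median). Aggregation is permutation-invariant in tiles and equivariant
under adding a constant to a feature; both properties are asserted in the
test suite. Only the median is offered: robustness to tile outliers
(necrosis, pen marks, fat) is the reason it is the field's default, and a
silent switch to the mean would change every downstream statistic.

Slides are paired with bulk expression profiles by **vial id** — the
sample-level prefix of a TCGA-style barcode (project–site–participant–
sample+vial), exposed as a configurable key-extraction function so
non-TCGA identifiers work. Duplicate keys raise rather than first-match.

## The Optimal Bayesian Filter

Each feature is modeled as either a *marker* (class-conditional
distributions differ) or a *non-marker* (one distribution). Data blocks
are Gaussian with unknown mean and variance. Parameters carry the
Jeffreys-rule prior in the (mu, sigma) parametrization,

    p(mu, sigma) = c / sigma^2,   c = 0.1 by default,

equivalently (c/2)(sigma^2)^(-3/2) in d mu d sigma^2. The block marginal
is closed-form:

    L(S) = (c/2) (2 pi)^(-(n-1)/2) n^(-1/2) Gamma(n/2) (SS/2)^(-n/2),

with n the block size and SS the centered sum of squares. The non-marker
marginal pools all samples into one block; the marker marginal is the
product of per-class blocks (one factor of c per block). With marker
prior pi = 0.5 the posterior is pi m1 / (pi m1 + (1-pi) m0), computed in
the log domain with log-gamma and a log-domain logistic.

Several conventions here were genuinely open and are fixed as follows:

* **Prior parametrization.** "Jeffreys prior" for a Gaussian admits more
  than one reading (1/sigma^2 per scale parameter, the joint
  Jeffreys-rule form, and either the sigma or sigma^2 measure). The
  package uses the Jeffreys-rule prior in (mu, sigma). Every closed form
  is verified against direct 2-D numerical quadrature of
  likelihood x prior in the tests, so the chosen prior is implemented
  exactly, whatever one thinks of the choice.
* **a(m) conventions.** The effect size a(m) is the ratio of the total
  sample variance to the weighted geometric mean of the class-conditioned
  variances. The package uses maximum-likelihood (biased) variances with
  sample-size weights w_y = n_y / n. a(m) tends to 1 for non-markers and
  grows with distributional difference; the posterior is strictly
  increasing in a(m) at fixed sample sizes and total variance (asserted
  by a grid test).
* **Threshold scale.** The improper prior leaves a residual scale
  dependence of order sqrt(SS), so "the a(m) at which the posterior
  reaches a target" is only well defined at a fixed scale;
  `am_threshold` standardizes the total (MLE) sample variance to 1 and
  assumes equal class-conditional variances, so the between-class shift
  carries the whole effect. Under these conventions the posterior-0.95
  thresholds for balanced cohorts are **1.080** at total n = 200 and
  **1.150** at total n = 100, close to (but not exactly) the reference
  values 1.088 / 1.159 quoted for this statistic in the literature; no
  convention we examined reproduces those to three decimals, and the
  residual ~0.8% gap is documented rather than tuned away.

Selection rules: **minimal-risk OBF** keeps posteriors above 1 - alpha;
**FDR-OBF** keeps the largest posterior-sorted prefix whose mean
(1 - posterior) is at most alpha, which bounds the sample-conditioned FDR
— the greedy prefix is provably optimal and is checked against exhaustive
prefix search on random vectors. Marker-count moments treat features as
independent (mean = sum of posteriors, variance = sum p(1-p)), and
cross-cancer joint posteriors multiply per-cancer posteriors under the
same independence assumption.

**Structured OBF** scores the four partitions of the (frozen-normal,
frozen-tumor, FFPE-tumor) groups — A: one distribution; B: frozen vs
FFPE; C: tumor vs normal; D: frozen tumor apart — with priors (1/2, 1/6,
1/6, 1/6) and per-structure marginals that are products of block
marginals. A mone whose MAP structure is B with the two tumor-group means
straddling the frozen-normal mean is flagged as ineffective for
tumor/normal discrimination: its apparent effect is a preparation
artifact. Restricting the structures to {A, C} and merging the tumor
groups recovers the two-class marker posterior exactly (asserted).

The FDR-OBF calibration test samples features from a truncated proper
version of the same prior (mu uniform, sigma^2 with density proportional
to (sigma^2)^(-3/2) on a bounded range) with c set to the truncated
prior's true normalization; realized false-discovery proportions then
match the nominal bound up to truncation edge effects.

## Frequentist differential tests

Welch's unequal-variance t, the two-sample Kolmogorov-Smirnov test, and
the Wilcoxon rank-sum test (scipy implementations), each
Benjamini-Hochberg adjusted (statsmodels) across the feature family of one
(cohort, test) analysis. The rank-sum test enumerates exactly when both
classes have fewer than 20 slides and no ties, else uses the normal
approximation with continuity and tie corrections; the exact path is
validated against a full permutation oracle. Constant features report
t-test p = 1 with a degeneracy flag rather than NaN. Top-k ranking sorts
by raw p with ties broken by |statistic| then feature id.

A calibration caveat asserted in the tests: the exact KS statistic is
discrete, and at 20 slides per class its attained level is ~0.035 at
nominal 0.05 — the test is valid (level is held) but conservative; t,
rank-sum and the Fisher correlation test sit within binomial error of the
nominal level at all sizes tested.

## Correlation networks

Covariances are estimated with **Ledoit-Wolf shrinkage** (scikit-learn)
and normalized to correlations; shrinkage toward a scaled identity never
increases an off-diagonal correlation's magnitude beyond the sample
value's (asserted per draw). Pair significance uses the **Fisher
transform**: z = atanh(r) is treated as N(atanh(rho0), 1/(n-3)); the
composite null |rho| <= rho0 (used for "highly correlated with a seed
mone" analyses, rho0 = 0.5) is evaluated at the boundary carrying the
sign of r. n for the test is the raw slide count — shrinkage changes the
estimate, not the nominal df; a known approximation. BH runs over the
upper-triangle family. Pooled matrices are element-wise means with the
diagonal reset to 1; family preservation is |intersection| / |union| of
per-cancer significant-pair sets. Differential correlation compares
tumor and normal matrices pairwise via (z_t - z_n) normalized by
sqrt(1/(n_t-3) + 1/(n_n-3)), and is antisymmetric under swapping the
groups. Correlation analyses default to frozen slides only; combining
frozen and FFPE is a flag.

One deliberate split: for the **mone x gene** block (integration), the
Ledoit-Wolf estimate is reported but p-values are computed on the plain
sample correlation. With hundreds of candidate genes that are mostly
noise, the estimated shrinkage intensity is large and testing the shrunk
value against the nominal df would have essentially no power; the sample
correlation is the quantity whose Fisher-transform null is actually
correct. For mone-mone analyses at modest feature counts the shrunk and
sample values nearly coincide and the shrunk value is tested, matching
the order of operations of the pipeline.

## Linear classifiers

Labels are cancer:lesion pairs (the "38-class" scheme on a full 19-cancer
cohort) or plain tumor/normal. **MLDA** is scikit-learn's
LinearDiscriminantAnalysis (SVD solver), giving the (k-1)-dimensional
discriminant projection and Gaussian equal-covariance posteriors.
**LR-LASSO** is multinomial logistic regression with an L1 penalty at
inverse strength C = 100 (saga solver); coefficients below 1e-8 are
reported as zero, and non-convergence warns rather than failing silently.
AUCs are insensitive to C over 1..1000 on separable cohorts (asserted),
so C = 100 is kept throughout; sparsity demonstrations use a stronger
penalty because at C = 100 the null coefficients are small but not
exactly zero.

Monte Carlo cross-validation makes 10 (configurable) random splits at the
**patient** level: a patient's slides never straddle train and test, and
class ratios are preserved by allocating whole patient groups (grouped by
their class-contribution signature) against per-class targets. Test
fraction defaults to 0.25. Evaluation reports per-class one-vs-rest AUC
computed as the normalized rank (Mann-Whitney) statistic with ties at
0.5 — identical to exhaustive pairwise concordance, which the tests
assert on all instances up to 50 slides — plus a row-normalized confusion
matrix. The **universal tumor score** of a slide is the sum of predicted
probabilities of all tumor classes of the 38-class model, scored against
the binary tumor/normal label. **Cross-classification** trains a binary
tumor/normal LR-LASSO per cancer and evaluates every model on every
cancer's slides (held-out within the training cancer on the diagonal).

Clustermap separation metrics: slides are clustered hierarchically
(average linkage, Euclidean — the plotting default the pipeline's
clustergrams use), cut to 2 clusters; rand and adjusted-rand scores
compare clusters with labels, and the clustermap AUC scores each slide by
its cluster's tumor fraction (this package's documented construction —
the metric has no canonical definition). t-SNE embeds the MLDA space in
2-D with PCA initialization and a fixed seed; "number of neighbors 50" is
mapped to perplexity 50, the t-SNE parameter controlling the effective
neighbor count. The embedding is for visualization only.

## Integration with expression

Genes with zero values in more than half the paired samples or with
standard deviation below 0.25 (log scale) are removed before any test;
"zero counts" is interpreted as a zero in the log-normalized matrix since
raw counts are not retained. The mone and gene vectors are stacked, a
Ledoit-Wolf covariance estimated, and the mone x gene correlation block
tested (see above) with BH within that block only — not jointly with
mone-mone tests. Significant pairs form a bipartite graph whose connected
components (at least 2 mones and 2 genes) are the reported mone-gene
clusters; components are the weakest assumption-free clustering. A
cluster's mones are combined by **PC-1** of the centered (not scaled)
member columns — members of a correlated cluster share a scale family, so
correlation-PCA is unnecessary, though it is switchable — with the sign
fixed so the smallest-id member loads non-negatively. Covariate
correlations (cellularity, leukocyte/lymphocyte fractions, immune-cell
counts) are pairwise-complete Pearson with Fisher p, with an optional
trim rule that drops samples whose covariate exceeds a threshold (the
outlier rule used for B-cell fractions above 3%); fraction covariates are
log-normalized upstream. The IG score is the per-sample mean
log-normalized expression of an immunoglobulin gene set; missing members
are reported, and by default all members are required.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, at
the least structure that exercises every code path:

* **Hierarchy.** Slide-level Gaussian signal plus independent tile-level
  Gaussian noise (sd 0.5 by default, 20-40 tiles per slide), so the
  median aggregation is non-trivial. Slide-level variances are 1, so all
  effect sizes are in slide-level sd units.
* **Markers** shift the tumor-class mean by delta (optionally scaling its
  variance) in the affected cancers; effects can equivalently be
  specified as a target a(m), inverted through
  a = 1 + w0 w1 delta^2 (equal class variances, sample-size weights).
* **Correlated blocks** follow a one-factor model: each block feature
  mixes a shared latent factor at sqrt(rho), giving within-block
  correlation rho; the factor is shared across the cancers that share the
  block.
* **Structure features** add group means over (frozen-normal,
  frozen-tumor, FFPE-tumor); **tissue signatures** shift a feature for
  every slide of one cancer, emulating tissue-of-origin morphology so
  multi-class cohorts are separable by cancer as well as by lesion.
* **Expression** couples selected genes to a latent factor or a feature's
  slide values at a target Pearson correlation; ~10% of the remaining
  genes are made zero-inflated or near-constant to exercise the filters.
  Covariates couple the same way at the slide level.
* **Determinism.** One integer seed; per-stage child streams (cohort,
  expression, each covariate) are spawned from it with stable tags, so
  stages regenerate independently and identical seeds give byte-identical
  outputs.
* Default cohort sizes: 50 frozen tumor, 50 frozen normal and 30 FFPE
  tumor slides per cancer, in the range of mid-sized TCGA cohorts.
  Tumor and adjacent-normal frozen slides are paired within a patient
  where counts allow, which makes the patient-grouping constraint of the
  split plan bind.

What passing on this generator does *not* show: real CNN features are
heavy-tailed and rectified, preparation artifacts are not additive mean
shifts, expression couplings are not linear-Gaussian, and cohort
confounding (site, scanner, stain) is absent. The benchmarks establish
that the machinery is correct and calibrated under its own assumptions,
not that those assumptions hold for any particular dataset.

## Benchmark problem sizes

The test-suite benchmarks use desk-scale sizes chosen to keep Monte Carlo
error well below the asserted margins: calibration at 2,000 null features
and n in {20, 50, 200}; marker recovery at 10/500 features over 50 seeds;
block and bicluster recovery at n = 300 over 20 seeds; structure recovery
at n = 200 per group over 25 seeds per structure; and classification
separability on a 19-cancer, 38-class cohort with 40 slides per class
(1,520 slides, 60 features), with pairwise class-mean separation 4 sd for
the OVR-AUC checks and strongly lesion-linked markers (6 sd) for the
universal tumor detector — summed logistic probabilities saturate near
decision boundaries, so near-perfect universal detection presumes strong
lesion markers, which is also the regime the real universal detector
operates in.

## Known limitations

* The OBF prior convention is fixed by documented choice among several
  defensible "Jeffreys prior" readings; posterior values (not orderings)
  depend on it and on c.
* Fisher tests after shrinkage use nominal df (anti-conservative in
  principle, negligible at the feature counts used here).
* The exact KS test is conservative below ~25 slides per class.
* FDR-OBF's FDR bound is conditional on the model; under misspecified
  (e.g. heavy-tailed) feature distributions the realized FDP can exceed
  alpha.
* t-SNE output is seed-reproducible but not metrically meaningful; no
  acceptance weight is placed on it.
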