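# Methods

This note records the models implemented in `vagitopics`, their
assumptions, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical choices
that matter for reproducing results.

## Data model and filtering

Counts live in a `CountMatrix`: a taxa × samples non-negative integer
table with Greengenes-style 7-rank lineage strings and per-sample clinical
metadata. Filtering follows the standard prevalence semantics: samples
need ≥ 1000 reads (`min_sample_reads`); a taxon is kept iff it has
≥ `taxon_min_count` reads in at least `ceil(taxon_min_prevalence · n)`
samples — defaults (2, 0.10), with a relaxed preset (1, 0.05) for
cross-region concordance work. The ceiling is computed as
`ceil(frac·n − 1e−9)` so that exact fractions (10% of 20 samples = 2) do
not round up through floating-point error. Agglomeration sums counts over
lineages truncated at genus or species; taxa with an empty value at the
target rank pool into one unassigned row per distinct parent lineage, and
the grand total is conserved exactly.

`log10_normalize` first rescales each sample to the median library size,
then applies log10(x + pseudocount) with pseudocount 1, so zeros map to 0
and stay distinguishable from low counts. Library-size scaling before the
log is this package's choice; it prevents sequencing depth from dominating
the Euclidean distances used downstream in clustering.

## Synthetic cohort generator

The generator implements the generative law the downstream analysis
presumes — the admixture (LDA) model:

* ω_i ~ Dirichlet(α₀ = 0.3 symmetric over K topics). The small
  concentration makes most samples strongly dominated by one community,
  the regime observed in vaginal microbiome cohorts.
* θ: in template mode (default), four topics with nearly disjoint
  supports — a *Lactobacillus crispatus*-dominant topic, an *L. iners*-
  dominant topic, a diverse BV-like topic spread over many anaerobe taxa,
  and a pathogen-enriched topic (*Granulicatella*, *Streptococcus*,
  *Fusobacterium*, *Veillonella*, *Anaerococcus*, ...). Near-disjoint
  supports make the mixture identifiable, which is what the parameter-
  recovery validation exercises.
* Library sizes L_i ~ round(LogNormal(8.5, 0.6)) — a typical post-QC 16S
  depth distribution (median ≈ 5000); counts_i ~ Multinomial(L_i, ω_i θ),
  so each sample's column total equals its drawn library size exactly.
* Clinical covariates: two enrollment sites, age ~ N(24, 4.5²) clipped to
  18–45, labor hours ~ Gamma(2, 13), parity ~ Poisson(2), and binary
  exposures at the cohort's prevalences. A small missingness rate (2%) is
  injected into the self-reported/assay binaries so imputation paths are
  exercised.
* Fever follows a logistic model on centered age (−0.20 per year),
  centered labor duration (ln 1.19 per 10 h), prior fever (ln 10.56), the
  pathogen-topic weight (ln 9.77 per unit weight — the printed magnitude
  of a per-unit-topic-weight odds ratio in this cohort), and a labor ×
  pathogen-topic synergy (ln 9.77 per unit weight per 10 centered labor
  hours): prolonged labor with a dysbiotic pathogen-dominated community
  raises fever risk beyond either factor alone. Because labor hours are
  centered, the synergy term is marginally almost silent — it is
  "combinatory" structure that only a model seeing both clinical and
  microbial features can exploit. The intercept is calibrated by
  bisection to a 50% fever prevalence, mirroring the 49/50 arm design at
  n = 99.

A separate epidemiologic generator (`generate_table1_cohort`) draws binary
exposures whose *population* cross-product odds ratio against fever equals
a target exactly, given the control-arm prevalence; finite-sample
estimates are random around it.

What the generator does **not** emulate: phylogenetic correlation between
taxa, compositional zero-inflation beyond the multinomial, batch and
primer effects, overdispersion of counts beyond the Dirichlet mixture, or
measurement error in clinical covariates. Passing the recovery tests
therefore shows the estimators are correct under the admixture model, not
that real cohorts satisfy that model.

## Community state typing

Hierarchical clustering uses Euclidean distance on log10-normalized
species abundances with complete linkage (the default of the heatmap
tooling standard in this literature; Ward is selectable) and cuts the tree
into k = 5 clusters. Labels are renumbered by first occurrence, making the
assignment deterministic given row order. The refinement pass computes a
per-taxon Kruskal–Wallis test across the initial labels, keeps taxa with
Bonferroni-adjusted p < 0.05 (family = number of taxa), and re-clusters on
the marker subset with the same k.

Caveat, documented deliberately: testing taxa against clusters fit on the
same data is circular. Under a truly homogeneous cohort the forced
clusters inflate the KW statistics, and at n ≈ 99 some taxa clear
Bonferroni in most null replicates. The refinement is useful for marker
curation — its purpose here — but the selection p-values must not be read
as calibrated evidence of community structure. The package's tests verify
calibration of the KW test itself under pre-specified (non-circular)
grouping.

The CMT–outcome association uses a chi-square test of independence on the
k × 2 table, switching to a Monte-Carlo permutation null (4999 draws) when
any expected cell is below 5.

## Grades-of-membership model

The model is the multinomial admixture p(s_i) = Σ_j p(s_i|z_i=j) p(z_i=j).
Two estimators are implemented:

* **MAP EM** (default): expectation-maximization with symmetric Dirichlet
  priors entering as pseudocounts (prior_ω = 1/K on sample weights,
  prior_θ = 0.1 on topic rows). This is the estimator family behind
  grades-of-membership fits of count matrices; it is deterministic given
  the seed, fast (vectorized over the count table), and its log-posterior
  trace is monotonically non-decreasing, which the test suite asserts.
  Restarts (default 3) guard against local optima; the best fit by final
  log posterior is kept.
* **Collapsed Gibbs**: token-level sampling with posterior-mean θ/ω from
  post-burn-in averaged counts (defaults 2000 sweeps, 500 burn-in, thin
  10). It is the reference sampler formulation, practical at modest depth;
  the suite cross-checks that both backends agree (matched-topic θ
  correlation ≥ 0.95) on separable data.

Label switching between fits is resolved by Hungarian matching on
row-wise Pearson correlations of θ.

**Topic-number selection.** The elbow statistic is the discrete second
difference f(K−1) − 2f(K) + f(K+1) of a decreasing criterion, maximized
over interior K. The default criterion is the negative model
log-likelihood across fitted K: for mixed-membership data the likelihood
flattens sharply at the true K, giving a crisp elbow. K-means
within-cluster inertia is selectable but demonstrably unsuitable here —
samples that are genuine convex mixtures of topics do not form point
clusters, so the inertia curve decays smoothly and its elbow lands at
K = 2 regardless of the planted K. An independent selector runs NMF
(multiplicative updates, Frobenius loss, nndsvda initialization) on
library-size-normalized counts and takes the elbow of reconstruction
error; on template cohorts both selectors agree on the planted K = 4.

Topic-taxon summaries are reported as row-wise z-scores of θᵀ (per taxon,
standardized across topics, sample sd), the convention of row-scaled
heatmaps in this field.

## Differential abundance

Per-sample size factors are DESeq-style medians of ratios to per-taxon
geometric means over all-positive taxa, normalized to geometric mean 1
(positive-part fallback with a warning when no taxon is positive
everywhere). Each taxon is fit with a negative-binomial log-linear model
(log size factor offset; design = intercept + fever [+ k−1 CMT indicators
+ site]); dispersion is per-taxon method-of-moments on normalized counts
with a 1e−8 floor, and inference is a Wald z test with Bonferroni
correction over the taxa actually tested. Non-converged or unstable fits
(SE ≥ 1000) are excluded from the family and reported as NA.

This is a deliberately lean reimplementation of the NB framework: no
empirical-Bayes dispersion shrinkage, no independent filtering, no outlier
replacement. Direction and significance — the quantities the scientific
claims rest on — are what the simulations validate: type-I error within
[0.03, 0.07] at nominal 0.05 on null NB data, and recovery of planted
4-fold changes. The batched IRLS engine is verified against statsmodels
GLM (same likelihood, independent optimizer) to ~1e−5. Taxa with an
all-zero outcome group get a Haldane-style +0.5-smoothed fold-change
*report*; their test still comes from the model.

Volcano classes follow the published rule: `nominal` for raw p < 0.05
only, `bonferroni` for adjusted p < 0.05. Cross-region concordance
tabulates direction agreement of taxa significant in either region.

## Association statistics

Odds ratios are cross-products with Woolf logit 95% CIs; the Haldane
+0.5 correction is applied on request when a cell is zero. Only point
estimates are comparable to published values — the published intervals'
shapes suggest profile-likelihood CIs, which this package does not
implement. Logistic regression is maximum likelihood via IRLS with
explicit separation detection. Spearman p-values use the t approximation
at n ≥ 10 and exhaustive permutation below. The topic–clinical scan
regresses each binary outcome on each topic weight (OR per unit weight),
correlates continuous variables with weights, and Bonferroni-adjusts with
m = number of topics per variable family. Missing clinical values are
handled pairwise per analysis throughout.

Cross-region per-taxon correlations restrict each taxon to the shared
samples where it is nonzero in both regions and report NA below 5
qualifying samples.

## Diversity and ordination

Shannon entropy uses the natural log; Simpson is the Gini–Simpson index.
Both operate on per-sample proportions, so they are invariant to depth
rescaling. Bray–Curtis dissimilarity defaults to relative abundances (a
raw-count variant is exposed; the two agree when totals are equal).
NMDS minimizes Kruskal stress-1 by SMACOF majorization with isotonic
regression, 20 seeded restarts, convergence at relative stress change
< 1e−6; coordinates are centered. The two-group diversity comparison is
Mann–Whitney (exact enumeration when both groups ≤ 8 and tie-free,
tie-corrected normal approximation otherwise), dispatching to
Kruskal–Wallis for more than two groups.

## Prediction

The feature table fuses the 11 clinical covariates, K topic weights and k
one-hot CMT indicators (11 + 9 = 20 at the default K = 4, k = 5). The
random forest uses 500 trees, √p features per split and unlimited depth by
default; splits are simple random 69-train/30-test partitions redrawn
until both classes appear in each side. Missing values are imputed by the
*training* split's median (continuous) or mode (binary) each round — the
test split never informs imputation, and a leakage canary in the test
suite verifies a feature informative only in test rows cannot raise AUC.
Reported quantities are the round-averaged AUC, a vertically averaged ROC
on a 101-point FPR grid, and impurity importances averaged over rounds and
normalized to sum 1. AUCs are round-averaged (not pooled), and identical
seeds give identical split sequences across feature sets, so feature-set
comparisons are paired.

The planted-effect ordering check — AUC(all) > AUC(clinical) >
AUC(microbial) — is evaluated on a 300-sample cohort drawn from the
default generative conditions, keeping the 69/30 split sizes. Two
design facts matter here. First, a purely *additive* logistic law cannot
produce a large fusion gain: discriminabilities add in quadrature
(d_all² = d_clin² + d_mic²), so a microbial-only panel at AUC ≈ 0.56
adds only ~0.01–0.03 ideal AUC to a ≈ 0.7 clinical panel — less than a
random forest's feature-dilution cost at 69 training samples. A
substantial fusion gain over a weak marginal microbial panel implies
clinical–microbial synergy, which is why the generator's fever law
includes the labor × pathogen-topic interaction; with it, the ideal
scores give AUC ≈ 0.85 (all) / 0.79 (clinical) / 0.57 (microbial-only).
Second, at n = 99 the cohort-level sampling noise of the realized
covariate–fever associations (± ~0.05 AUC) still swamps the regime, so
the ordering is resolved on a cohort large enough for realized
associations to approach their population values.

A related finite-sample artifact worth knowing: when every resampling
round partitions the entire cohort (n_train + n_test = n), the train and
test noise associations of each feature are negatively coupled given the
cohort's fixed labels, and a forest that overfits training noise scores
*below* 0.5 AUC under the null (anti-learning; ≈ 0.40 at n = 99 with 20
noise features). Null calibration is therefore assessed on a cohort
larger than the split sizes.

## Problem sizes used in validation

Parameter recovery runs at N = 150 samples, ~60 taxa, median depth ≈ 3000,
K = 4; topic-number recovery over 20 seeded replicates of the same scale;
NB type-I calibration over 500 null replicates of 50 taxa × 100 samples;
the RF ordering at 200 resampling rounds with 300 trees (80 rounds with
200 trees in the routine test suite); the pipeline's default RF
configuration is scaled likewise (200 rounds) with the full 1000-round,
500-tree setting available through `AnalysisConfig`.
These sizes are the package's validation choices: large enough for each
property to resolve, small enough to run routinely.

## Known limitations

* The NB engine's method-of-moments dispersion is noisier than shrinkage
  estimators at low counts; its Wald tests are mildly anticonservative for
  very low-abundance taxa.
* The GoM likelihood surface is multimodal; restarts mitigate but do not
  eliminate local optima at small depth.
* The CMT refinement's selection p-values are circular by construction
  (see above).
* Woolf CIs, not profile-likelihood; exact logistic regression and
  conditional (Fisher) odds ratios are out of scope.
* NMDS stress depends on restarts for non-embeddable configurations;
  comparisons across dissimilarity transforms are approximate (rank
  invariance holds to ~1e−2).
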