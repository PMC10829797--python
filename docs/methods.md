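# Methods

`proteosubtype` re-implements, as a tested library, the analysis arc of a
proteogenomic AML study: TMT quantification processing, multiomic subtype
discovery, proteome-based subtype classification, functional enrichment,
ex vivo drug-response stratification, and per-drug AUC prediction. This
note records the models, the defaults that matter, and the design choices
made where the procedure was genuinely open.

## Quantification preprocessing

**Relative abundance.** TMT reporter intensities are converted to
log2(sample / pooled-reference) ratios per feature and zero-centered
across samples. Features with a nonpositive reference intensity are
undefined and returned as all-NA.

**Missingness filter.** A feature is kept when it is observed in at least
half the samples; the boundary is inclusive (missing fraction ≤ 0.5
survives), reading "present in at least 50%" literally.

**Median polish.** Tukey's alternating row/column median removal, iterated
until the largest removed median falls below `tol` (default 1e-8, max 50
sweeps); NA entries are ignored by every median and preserved. Because it
is ambiguous whether a published "median polish" means the full two-way
polish or a single per-axis centering pass, both are provided
(`mode="polish"` / `mode="center"`); polish is the default. Even-count
medians use the mean-of-middle-pair convention.

**Plex completeness.** A TMT plex counts as missing for a feature when
every sample in that plex is NA. The strict rule (`max_missing_plexes=0`,
at least one measurement per plex) matches global-proteome processing;
the relaxed rule (e.g. ≤ 10 of 21 plexes missing) is the phosphosite
variant. `apply_global_loading_normalization` subtracts the per-sample
median offsets of the global proteome from the phospho matrix so both
modalities share one loading correction.

**KNN imputation.** Each NA is replaced by the mean of the `k = 10`
nearest feature rows, with Euclidean distance computed over co-observed
samples and candidate neighbors required to be observed at the target
sample; features without an eligible neighbor fall back to their row
mean. The distance metric and `k` are configurable because the upstream
tool's exact settings are unpublished; feature-space KNN is the
documented mode of that tool.

**Empirical-Bayes covariate correction.** Per feature, abundance is
regressed on a centered design (standardized continuous covariates plus
centered one-hot categorical levels). Each coefficient b_f is shrunk
toward the across-feature mean with weight τ²/(τ² + se_f²), where τ² is
the method-of-moments between-feature coefficient variance
(Var(b) − mean(se²), floored at 0). The shrunken fitted covariate effect
is subtracted; feature means are preserved because the design is
centered. With `shrink=False` this reduces exactly to per-feature OLS
residualization, which is the property the tests pin down. The reference
implementation's exact prior is not restated in the literature we
implement from, so the shrinkage weight is our choice; at cohort scale
(hundreds of samples, tiny standard errors) the weight is ≈ 1 and the
choice is immaterial.

**Covariate effect scan.** Continuous covariates: per-feature correlation
t-test; categorical: one-way ANOVA; BH adjustment across features and the
fraction with adjusted p < 0.05 reported. This is the diagnostic used to
show that nearly all features carry a loading-mass effect before
correction and about the nominal 5% after.

## Subtype discovery (signed-split consensus NMF)

Each imputed modality is z-scored per feature (zero-variance features
dropped), then split by sign: every feature contributes a nonnegative
positive-part row and negative-part row, doubling the row count, and
modalities are stacked. Z-scoring is per feature, so its order relative
to concatenation is immaterial.

Factorization is multiplicative-update NMF under the generalized
Kullback-Leibler divergence (the classic Lee-Seung/Brunet updates, the
default algorithm of the standard NMF package), initialized uniform-
random scaled by √(mean(X)/k). The update rule guarantees a
non-increasing objective; the implementation records the objective every
iteration and the tests assert monotonicity. Samples are labeled by the
argmax row of H (ties to the lowest index).

For each candidate rank k the factorization is restarted `n_runs` times
(seeds = base + run index); the consensus matrix A averages the
co-membership indicators. Final labels cut the average-linkage dendrogram
of 1 − A at k — consistent with the cophenetic statistic — rather than
taking a single representative run (both are available). The rank is
chosen to maximize the cophenetic correlation between 1 − A and the
dendrogram's ultrametric distances, ties to the smaller k; the default
scan is k = 2..8. Mutation (WES) data are excluded from clustering
because binary mutation indicators are far too sparse to carry the
factorization.

## Proteome-only subtype classifier

A multinomial logistic model with elastic-net penalty
λ[(1 − α)/2‖β‖₂² + α‖β‖₁] on standardized features (solver:
scikit-learn SAGA; symmetric softmax parameterization). α is evaluated
on a grid by stratified repeated 5-fold CV and chosen to maximize the
mean recall of the hardest subtype (the class with the lowest overall
recall), ties to the larger — sparser — α; the study-motivated default
is α = 0.9. λ is the minimizer of mean CV multinomial deviance along a
log-spaced path (default 30 points spanning three decades below the
gradient bound λ_max; a longer path is available but adds little at
cohort scale). The number of CV repeats defaults to 5 and is
configurable since "repeated" leaves it open.

Prediction standardizes new samples either with the training statistics
(default; makes a training centroid classify to its class) or with the
new cohort's own statistics (`stats="self"`), which mirrors the cell-line
application procedure of standardizing the external dataset and
mean-imputing anything missing; in both modes missing features contribute
0 after centering. Probabilities are softmax scores summing to one.

## Functional enrichment

Per-subtype ranked lists are built by mean-centering every feature and
averaging the centered values within the subtype. Preranked GSEA uses the
weighted KS running sum (hit increments ∝ |score|^w with w = 1, miss
decrements 1/(N − N_hits)); ES is the extremum of the running sum and is
evaluated only at hit positions (an O(m) identity of the running sum,
cross-checked in tests against the direct O(N) walk). Significance is by
feature-label permutation — the null ES of a size-m set is the ES of m
random features — with p two-sided on |ES| with the +1 correction, and
NES = ES / mean|null ES|. The permutation count defaults to 1000, set
size bounds to [5, 500], and nulls are cached per set size. The reference
tool's multilevel p estimation is out of scope; the scheme is recorded in
the result metadata. BH adjustment runs across sets.

KSEA is the kinase z-statistic z = (m̄_s − m̄_p)·√m / δ with m̄_s the mean
substrate score, m̄_p and δ the mean and SD of all quantified sites
(sample SD), two-sided normal p, BH across kinases. A zero background SD
yields NaN.

Note on calibration: permutation and exact tests are discrete, so their
null p-values are uniform only up to the support spacing; the calibration
tests use large backgrounds (and for Fisher, large tables with varying
prevalence) so the spacing is fine relative to the KS resolution.

## Drug-response stratification

AUC values live in [1, 300], lower = more sensitive; a drug enters the
analysis only if assayed on ≥ 100 samples with ≥ 10 samples strictly
below AUC 100 (the "sensitive" criterion). Group comparisons are Welch
unequal-variance t-tests with the sign convention positive = group of
interest more resistant; subtypes are tested one-vs-rest. BH adjustment
spans all (drug × grouping) tests of an analysis jointly by default (a
per-drug scope is behind a flag), and samples with co-occurring mutations
are not excluded. Subtype × mutation interactions are within-subtype
mutant-vs-wild-type Welch tests under the same joint BH family, starred
by order of magnitude (p ≤ 0.01 → "*", ≤ 0.001 → "**"). Cluster
enrichment of binary annotations is the two-sided Fisher exact test at
p < 0.05. Survival uses Kaplan-Meier curves per subtype and the k-group
log-rank test (lifelines).

## Per-drug AUC regression

Elastic net (squared loss; λ by inner 5-fold CV on an explicit path so
the pure-ridge end α = 0 also works; α default 0.5) and LightGBM
gradient-boosted trees (500 rounds, learning rate 0.05, 31 leaves, early
stopping after 50 stale rounds on a 20% inner split — configurable and
logged, as the reference hyperparameters live only in a supplement).
Reproducibility is estimated by 5× repeated 5-fold CV — 25 held-out
Pearson correlations per drug; a drug counts as "robustly modelable"
above a configurable mean-r cutoff (default 0.3), since the original
criterion is unstated. The final signature refits on all samples and
takes nonzero coefficients (EN) or positive importances (GBT). External
samples (e.g. resistance trajectories) are predicted by an ensemble of 5
fold-complement models, giving a per-sample prediction range summarized
as median/min/max; missing features are imputed with training means.
2-D landscapes embed samples over a signature's z-scored features with
UMAP (delegated; seeded).

## Synthetic cohorts

The generator plants the statistical structure the analysis assumes, so
every stage is testable without the controlled-access patient data.
Defaults emulate the reference cohort geometry: n = 160 samples with all
three modalities, k = 4 balanced subtypes. Per modality each feature's
subtype means are N(0, 1) ("subtype_effect_sd", abundance units), with
N(0, 1) residual noise, additive per-(feature, plex) offsets N(0, 0.3)
over 8 round-robin plexes, and a per-feature loading-mass slope
N(0, 0.6)/µg over masses U(30, 70) µg — strong enough that the
pre-correction scan flags essentially all features, as observed for real
TMT data. Missingness is MCAR at rate 0.05 plus a logistic
intensity-dependent (MNAR) term rising to `mnar_strength` = 0.15 for
low-abundance entries, so imputation is exercised nontrivially. The
default feature counts (100 per modality) are deliberately modest; they
preserve the cohort's statistical geometry (aggregate subtype separation
scales with √features) while keeping consensus-NMF scans tractable, and
all counts are configurable.

Mutations are per-subtype Bernoulli flags (FLT3-ITD enriched in subtype
2, NPM1 in subtype 4, ...); drug AUCs are baseline + subtype shift +
mutation shift + noise, clamped to [1, 300], with each drug assayed on a
random fraction of samples; the default panel includes a subtype-2-
sensitive drug, a subtype-3-sensitive drug, a subtype-2 + FLT3-ITD drug,
a mutation-only drug, and four inert drugs. Survival is exponential with
per-subtype hazard multipliers (subtype 4 advantaged) around a 500-day
median and independent U(0, 1500)-day censoring; loading mass, plex
assignment, and the survival law are our own modeling choices, as no
generative description exists for them. Resistance trajectories
interpolate linearly between two subtype mean profiles over `n_stages`
stages with low within-stage noise, emulating the homogeneity of
cell-line replicates; they carry no batch structure.

What the generator does *not* emulate: feature-feature correlation
(pathway co-regulation), heavy-tailed abundance distributions, plex ×
feature interactions beyond additive offsets, informative censoring, and
dose-response curve fitting (AUCs are generated directly). Passing tests
therefore demonstrate the pipeline's correctness and calibration under
the assumed generative structure, not performance on real cohorts.

## Numerical choices

- NMF: ε = 1e-12 guards all divisions; convergence when the relative KL
  change ≤ tol (default 1e-6; consensus scans use 1e-4 with max 150-500
  sweeps, which the recovery experiments show is ample at cohort scale).
- Hierarchical clustering of 1 − A uses average linkage everywhere, so
  the label cut and the cophenetic statistic describe the same
  dendrogram; a constant A has no defined cophenetic correlation (NaN).
- Argmax/tie rules: H-column ties → lowest cluster index; α ties →
  larger α; k ties → smaller k.
- Standardization always uses ddof = 0 within estimators and stores
  train-side statistics on the fitted model.
- BH is applied once per declared family; NA cells are excluded from the
  family rather than imputed.

## Acceptance script problem sizes

`scripts/acceptance.py` regenerates everything from scratch at the
default study conditions; the model-order recovery rate uses a 5-seed
scan with 20-30 NMF restarts per rank — enough to make rank selection
stable at this cohort geometry — and the regression block uses an
n = 150, SNR-10 linear design with 6 features (5 informative).
Coefficient recovery is measured as the relative l2 error of the
standardized-scale coefficient vector; the aggregate error of any
(near-)unbiased fit scales as sqrt(p / (10 n)) at this SNR, which is why
the design keeps p small relative to n.
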