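# Methods

`tmedyn` re-implements, as a tested pipeline, the statistical machinery of
a serial-biopsy neoadjuvant-chemotherapy (NAC) immune-dynamics analysis:
longitudinal mixed-model differential expression, single-sample signature
scoring, nu-SVR immune deconvolution, integrative immune-state
classification, NMF virtual microdissection, H&E-style TIL quantification
and outcome association. The controlled-access patient cohort behind the
original analysis is not an input; every component is instead exercised on
a synthetic cohort generator whose ground truth is retained, so each
method's claims are tested as recovery of planted structure.

## The synthetic cohort generator

`simulate_cohort` draws patients with four clinical breast-cancer subtypes
(default proportions 0.22 / 0.20 / 0.20 / 0.38 for ER+/HER2−, ER+/HER2+,
HER2+/ER−, TN) and a 38% pathologic-complete-response (pCR) rate, sampled
at up to three time points: T1 (pre-treatment), T2 (after the first
treatment cycle) and T3 (surgery). pCR patients never receive a T3 sample
— surgery specimens exist only when residual disease is present — and
residual-disease patients additionally drop out of T3 with probability
0.10. Log2 expression of gene *j* in sample *i* follows the
random-intercept model

    y_ij = β0_j + β1_j·purity_i + β2_j[subtype_i] + β3_j[time_i]
           + b_patient(i) + ε_ij,

with `b ~ N(0, σ_b²)` and `ε ~ N(0, σ_e²)` (defaults σ_b = σ_e = 0.5 log2
units), exponentiated to a TPM-like scale via `2^y`. Effects are planted
on named gene blocks (immune, cell-cycle, EMT/ECM by default) with
time-profiles mirroring the up–down and down–up trajectories the design
emulates. Tumor purity is drawn Beta(5, 2) at baseline and Beta(4, 3)
on-treatment/at surgery — biopsies taken during response carry less tumor
— the magnitude of that drop being a free design choice.

What the generator does **not** emulate: negative-binomial count
dispersion (expression is log-normal by construction), gene–gene
correlation beyond block structure, realistic H&E stain chemistry, and
missingness beyond the T3 rule. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to every pathology of real RNA-seq or histology
data.

Three sibling generators provide the remaining inputs:

* `simulate_mixtures` — linear cell-type mixtures `signature @ f` with
  Dirichlet(1) fraction vectors and optional truncated Gaussian noise;
  `default_signature_matrix` ships a synthetic 13-profile leukocyte
  reference (20 markers per type at ~100 TPM against a ~2 TPM
  background) standing in for references derived from sorted immune
  cells.
* `simulate_histology_image` — a light textured tissue region on a
  near-white slide, with lymphocytes as small round dark nuclei (planted
  areas 70–140 px, inside the 60–150 detection gate) and non-lymphocytes
  as larger (>200 px) irregular, lighter nuclei. Grayscale-on-RGB
  caricature: the detector works on intensity and shape, which is what
  the stated filters exercise.
* `simulate_state_cohort` — paired T1/T2 samples with planted cold/warm/
  hot immune states. State mean patterns are affinely independent
  directions (not a pure intensity shift) so three clusters genuinely
  span two latent dimensions; the overall mean still increases from cold
  to hot, keeping the intensity ordering planted. T2 states follow a
  Markov transition biased toward warming.
* `simulate_outcome_panel` — per-patient features where only
  on-treatment (T2) features carry outcome signal (log-odds effects 2.0
  down to 1.0 over 8 features, against 8 baseline noise features,
  n = 120). The panel is sized so the planted baseline-vs-on-treatment
  contrast is testable by an 8-vs-8 exact rank-sum test.

All generators are bit-reproducible given their seed.

## Mixed-model differential expression

`fit_lmm` fits the single-random-intercept model by profiling: for a
candidate variance ratio θ = σ_b²/σ_e², the marginal covariance is block
diagonal with blocks I + θJ per patient, so the GLS fixed effects and the
profiled σ_e² are closed-form; the outer problem is a bounded scalar
search over log θ (with an explicit θ = 0 boundary check, where the model
collapses to OLS). ML and REML criteria are supported; fits agree with
`statsmodels` MixedLM to ~1e−6, which the test suite asserts, at roughly
three orders of magnitude less cost per gene (group-sum sufficient
statistics are precomputed once per design).

`run_de` analyzes each pairwise time comparison (T1–T2, T2–T3, T1–T3)
within each sample group (overall cohort, and per subtype when requested
and ≥3 patients). Purity is always a covariate; subtype is a covariate in
the overall group only. The time term is tested by a likelihood-ratio
chi-squared test of nested **ML** fits (REML likelihoods are not
comparable across fixed-effect structures). FDR is Benjamini–Hochberg
within each comparison × group; whether to pool instead is configurable
in principle but per-stratum is the default. Time is categorical — the
non-monotone trajectories the design emulates rule out a linear time
code. Differentially expressed genes are the union over strata of
`p < 0.01` and |log2 fold change| > 1 (fold change > 2 linear).

Consensus clustering of DE genes runs k-means (k = 3, 10 restarts) on
per-time means of gene-wise z-scored expression — z-scoring first makes
temporal *shape*, not amplitude, the clustering signal — over 100
resamples of 80% of samples; the consensus matrix of co-assignment
frequencies is cut by average-linkage hierarchical clustering. A pathway
maps to a gene cluster when hypergeometric enrichment FDR < 0.20 **and**
its signature score is differentially distributed over time at FDR <
0.05 (ties to the smallest enrichment FDR).

## Signature scoring

Scores are GSVA-style: per gene, a Gaussian-kernel ECDF statistic across
samples (bandwidth sd/4); per sample, genes ranked by that statistic;
per set, a weighted Kolmogorov–Smirnov-like random walk with symmetric
rank weights |(p+1)/2 − rank| and exponent τ (default 1). The score is
max-positive minus max-negative walk deviation (`max_diff`, default) or
the single largest-magnitude deviation. Centering the weights at
(p+1)/2 makes the score exactly antisymmetric under ranking reversal,
which the tests exploit. The cytolytic activity (CYT) score is the
geometric mean of GZMA and PRF1 expression with a 0.01 offset
(configurable), the convention of the cytolytic-activity literature.

## Deconvolution

`nusvr_deconvolve` regresses each bulk sample on the reference signature
with a linear-kernel nu-SVR over ν ∈ {0.25, 0.5, 0.75}, choosing ν per
sample by RMSE between fitted and observed values; mixture and signature
columns are jointly z-scored (which absorbs any positive scaling of the
mixture), negative coefficients are zeroed and the remainder normalized
to relative fractions. Deconvolution operates on linear TPM restricted
to the shared signature genes (at least half must be present).
`aggregate_cell_types` folds the 13 reference profiles into 10 reported
groups via a configurable mapping (default: merge naive/memory B cells;
naive CD4 with Tregs; monocytes with M0 macrophages).

## Immune states

`integrative_cluster` implements the Gaussian latent-variable formulation
of integrative clustering: standardized feature blocks are stacked and
modeled as X = W Z + ε with k−1 shared latent factors, fit by EM with a
lasso-type soft-threshold (default penalty 0.2; the pipeline's small demo
feature set uses 0.05) applied to the loadings each M-step;
initialization is deterministic from the leading principal components.
Assignments come from k-means (10 restarts, seeded) on the posterior
latent means. BIC = −2·loglik + (#nonzero loadings + #noise variances)·
log n selects k, with ties — including the floating-point ties that arise
when extra latent dimensions are entirely shrunk away — broken toward
smaller k. With k = 3 the clusters are ordered into cold/warm/hot (C/W/H)
by mean immune intensity; the pipeline's intensity summary is z-scored
CYT plus the z-scored sum of stimulatory cell fractions (CD8 T, CD4
memory, M1). Exactly tied cluster means raise an error rather than
silently picking an order. State transitions across paired time points
are tabulated with margins preserved, and per-edge percentages computed
with the same half-away-from-zero rounding used for all printed
percentages.

## Virtual microdissection

`nmf_brunet` factorizes log2(TPM+1) by KL-divergence multiplicative
updates from uniform random non-negative starts. Convergence is declared
when the sample connectivity vector (argmax factor per sample) is
unchanged for 40 consecutive checks at a 10-iteration interval, or at
`max_iter`; the KL objective is non-increasing by construction and the
tests verify it. Thirty runs are performed by default and the lowest-KL
factorization kept. Rank selection maximizes the cophenetic correlation
between 1 − consensus (sample co-clustering over runs) and the cophenetic
distances of its average-linkage tree; a degenerate all-identical
consensus scores 1 and is flagged.

Exemplar genes: per gene, the factor-specificity score
1 + (1/log2 k)·Σ p_f log2 p_f with p_f the row-normalized gene weights
(1 = single-factor, 0 = uniform). A gene is an exemplar iff its score
exceeds median + 3·MAD (MAD unscaled — no 1.4826 normality factor) and
the maximum of its **raw** W row exceeds the median of all W entries;
row-normalizing before the contribution test was the open alternative,
raw entries follow the cited extraction convention. Factors are
attributed to compartments (tumor-intrinsic / TIL / stromal / normal) by
the labeled sample group with the highest mean factor weight, vetoed when
exemplar pathway enrichments point elsewhere; tumor and normal factor
weights are summed into composite F-Tumor and F-Normal.

## TIL quantification

Segmentation is global Otsu on inverted intensity with minShape = 50,
maxShape = 800 and failureRegion = 2000 pixels: components under
minShape are dropped, components above failureRegion are segmentation
failures, and components in (maxShape, failureRegion] are split by
watershed on the distance transform with pieces re-filtered (pieces
still above maxShape after one split are kept — repeated splitting would
shred genuinely large nuclei). When the global threshold captures more
than 25% of the image it has separated slide from tissue rather than
tissue from nuclei (nuclei are sparse); thresholding is then repeated
within the tissue pixels, accepted only if the second threshold clears
the tissue median by 3 robust standard deviations — otherwise the image
is declared nucleus-free rather than carving texture noise.

Each candidate gets a fixed, documented 36-feature vector (12 shape
features from the re-segmented nucleus mask, 6 intensity statistics per
RGB channel, 6 texture summaries); the feature list approximates the
classic cell-feature sets by content and count, and classifier quality on
synthetic nuclei — not feature-list fidelity — is the tested surface. A
C-type radial-kernel SVM with Platt probability outputs is trained on a
few hundred cells pooled from synthetic training images labeled against
planted truth (`train_default_classifier`), the order of magnitude of a
hand-marked training set. The published filters are applied verbatim:
lymphocyte iff predicted lymphocyte, area ∈ [60, 150] px and probability
≥ 0.97; non-lymphocyte iff probability ≤ 0.1 (the band between is a
deliberate dead zone); large cell iff not predicted lymphocyte and area ≥
Q3 of areas among cells larger than 200 px.

Large images are processed in 2050-px tiles read with a 64-px overlap so
boundary nuclei are seen whole by at least one tile; a cell is kept only
by the tile owning its centroid, which resolves border duplicates.
Tissue area is the count of pixels darker than the Otsu
background-vs-tissue threshold, converted to mm² at a configurable scale
(default 0.5 µm/px, the 20× convention); TIL density is lymphocyte count
divided by tissue area.

## Outcome models

Single-feature associations adjust for the clinical covariate panel:
logistic regression (IRLS, Wald p) for binary outcomes, OLS otherwise,
with a ridge-penalized fallback flagged on perfect separation. Feature
ranking uses elastic-net bootstrap usage: per iteration, patients are
resampled with replacement (redrawn if the outcome degenerates),
features standardized on the resample, and an elastic-net logistic path
(α = 0.5, equal penalty factors for all variables) fit with the penalty
chosen by 5-fold cross-validated deviance under the one-standard-error
rule. CV folds are split on *source patients*, so rows duplicated by the
bootstrap never straddle folds — row-level folds leak duplicates,
selecting near-zero penalties and pushing noise-feature usage above 90%,
which destroys the ranking the procedure exists to produce. Usage is the
percent of iterations with a non-zero coefficient; ranks break ties by
mean absolute coefficient, then name. The reference setting is 10,000
iterations; tests and the acceptance script run 100–500 (the count is
recorded in the output). Baseline-vs-on-treatment usage groups are
compared by a two-sided Wilcoxon rank-sum test (exact at small n).

## Numerical choices and degenerate inputs

* Printed percentages round half-away-from-zero (Decimal arithmetic);
  banker's rounding breaks several printed values.
* Zero-variance rows z-scale to zeros with a warning; gene sets with no
  genes in the matrix score NaN with a warning; constant fraction columns
  yield NaN correlations.
* The LMM optimizer brackets log θ in [−12, 8] and always compares
  against the θ = 0 boundary; rank-deficient designs error and name the
  aliased columns.
* NMF guards all divisions at the smallest positive double; all-zero gene
  rows are dropped with a warning.
* Every stochastic routine takes an explicit seed; the pipeline fans one
  global seed into per-stage seeds by fixed offsets and records the
  config hash and all seeds in `summary.json`.

## Problem sizes

Tests and the acceptance script use deliberately desk-scale problems:
200 patients × 600 genes for mixed-model recovery, 30 Dirichlet mixtures
over 13 cell types, twenty 2050×2050 px images with 50–200 planted
lymphocytes, a 60-patient paired state cohort, 500 bootstrap iterations.
These sizes give stable Monte-Carlo estimates for every asserted property
while keeping a full run in minutes on one CPU.

## Known limitations

* The LRT for fixed effects uses the asymptotic χ² reference; at very
  small cohort sizes it is mildly anticonservative (the calibration test
  pins the type-I error only at n = 200 patients, 2 time points).
* GSVA scores are implemented in the continuous-data (Gaussian kernel)
  flavor only; a Poisson-kernel variant for counts is out of scope.
* The shipped deconvolution signature and SVM classifier are synthetic
  stand-ins; applying either to real data requires a real reference
  matrix / training set supplied by the user.
* `attribute_factors` is a rule-based helper; on real cohorts factor
  attribution ultimately needs judgment over enrichments and external
  signatures.
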