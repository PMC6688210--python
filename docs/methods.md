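# Methods

## The problem

Epigenome-wide association studies (EWAS) on Illumina methylation arrays are
confounded by population stratification: allele frequencies differ between
ancestral populations, many array probes sit on or near polymorphisms, and
methylation itself is under genetic control at mQTL loci. When self-reported
ethnicity is missing or unreliable — common in placental cohorts assembled
retrospectively — ancestry must be inferred from the methylation data
themselves. `methylancestry` implements a supervised approach: a penalized
multinomial classifier over beta values that returns, per sample, a
probability of African, Asian, or Caucasian ancestry, with a confidence
threshold that flags probable mixed-ancestry samples as Ambiguous.

## Model

Given beta values x_i for sample i and class label y_i ∈ {African, Asian,
Caucasian}, the classifier is multinomial logistic regression with an
elastic-net penalty in the glmnet parameterization:

    min  −(1/N) Σ_i log softmax_{y_i}(β0_c + β_c · x_i)
         + λ Σ_c [ (1−α)/2 ‖β_c‖₂² + α ‖β_c‖₁ ]

* symmetric softmax over all three classes (no reference class); the L1
  term makes the slope parameters identifiable, the intercepts are centred
  to sum to zero;
* intercepts unpenalized; features standardized with training means/SDs for
  fitting, coefficients reported back on the raw beta scale;
* α ∈ (0, 1] mixes lasso and ridge, λ ≥ 0 scales the penalty. Both are
  tuned by repeated stratified k-fold cross-validation minimizing the
  held-out log loss (accuracy and Cohen's kappa are selectable).

The solver is a monotone FISTA (proximal gradient with Nesterov momentum):
the smooth part (negative log-likelihood + ridge) is stepped with a fixed
step size 1/L, where L = σ_max(X_aug)²/(2N) + λ(1−α) bounds the softmax
Hessian, and the L1 part enters by soft-thresholding. Momentum restarts
whenever the objective would rise, so the objective sequence is
non-increasing. Convergence is declared when the relative objective change
falls below `tol` (default 1e−7) or after `max_iter` passes (default 10⁴).
The test suite verifies the fitted objective against an independent convex
solve (scipy L-BFGS-B on the positive/negative split of the coefficients)
to ~1e−12.

A sample's call is the argmax class when the maximum membership probability
is **at or above** the confidence threshold (default 0.75), else Ambiguous.
The threshold boundary is inclusive: a maximum of exactly 0.75 is a
confident call. Ambiguous calls count as incorrect in headline accuracy; an
excluding-ambiguous accuracy is reported alongside.

## QC cascade

Preprocessing runs, in order, each step producing a report of the exact ids
removed:

1. **Platform overlap** — only probes present on both the 450K and EPIC
   arrays (manifest flag) are retained, so models transfer across array
   generations. SNP probes are never dropped here.
2. **Quality filter** — a measurement fails when detection p > 0.01 or bead
   count < 3; a site is removed when strictly more than 1% of samples fail.
   Surviving failed measurements are set to missing.
3. **KNN imputation** — each missing value is replaced by the mean of the
   k = 10 nearest sites' values at that sample; nearness is nan-aware
   Euclidean distance between site profiles with the standard
   √(total/observed) rescaling (sklearn's `KNNImputer`, sites as rows).
4. **Flagged sites** — cross-hybridizing and tissue-non-variable probes are
   removed. SNP probes are exempt from the non-variable flag: their
   "variability" is genotype, which is exactly the ancestry signal.
5. **Sample QC** — (a) inter-array correlation: samples whose mean Pearson
   correlation with the rest falls below 0.95 are removed iteratively
   (worst first, recomputing), capped at 20% of the cohort so a
   batch-level problem is reported rather than silently decimated. A
   threshold of 0 disables the filter. (b) sex concordance: 2-cluster
   average-linkage hierarchical clustering on sex-chromosome betas, the
   cluster with higher mean chrY methylation labelled male; samples whose
   inferred sex contradicts the reported sex are removed. Correlation runs
   before the sex check because a grossly aberrant array has no coherent
   sex-chromosome signal and would cluster arbitrarily.
6. **BMIQ** — per sample, 3-state beta mixtures (unmethylated /
   hemimethylated / methylated) are fitted by EM to the type I and type II
   CpG distributions (quantile-thirds initialization, weighted
   moment-matching M-step, ≤100 iterations, tolerance 1e−6); type II
   values map through the fitted type II mixture CDF and back through the
   inverse type I mixture CDF (evaluated on a 2001-point grid). The map is
   monotone, so within-sample ranks among type II probes are preserved;
   type I values and SNP probes pass through unchanged. Skipped with a
   warning below 500 probes of either design.

All thresholds are configurable; the defaults above are the standard ones.

## Evaluation

Leave-one-dataset-out cross-validation (LODOCV) holds out an entire cohort
per fold: site filters, hyperparameter tuning, and the final fit see only
the training cohorts. Because BMIQ and the mixture fits are strictly
per-sample, held-out samples are normalized with their own fits — no
quantity estimated from the held-out cohort enters training. Held-out
measurements missing after restriction to the training site set are filled
with training site means. Aggregate metrics pool all held-out predictions;
this estimates cross-study generalization, which is the realistic deployment
setting, and is systematically harsher than pooled k-fold whenever cohorts
carry batch effects.

Metrics: accuracy (with and without Ambiguous counted against), Cohen's
kappa, per-class and macro positive predictive value, and log loss with
probabilities clipped to [1e−15, 1−1e−15]. Paired classifiers are compared
by McNemar's test with continuity correction, (|b−c|−1)²/(b+c) against
χ²(1), falling back to the exact binomial when b + c < 25.

## Population-structure comparison

Methods that reduce to site subsets (classifier-selected sites, the 59 SNP
probes, variant-distance filters at 0/1/2/5/10/50 bp, user-supplied lists)
are compared by PCA on per-site standardized betas within each cohort,
followed by simple OLS of each of the top 10 PCs on ethnicity (full
indicator expansion), genetic-ancestry coordinates (coordinates 1+2 jointly
and singly), and nuisance covariates, reporting R² per PC. For
classifier-selected sites, the sites used in a cohort come from a model
trained with that cohort held out, so the same samples never both choose
the sites and score them. PC signs follow a deterministic rule (largest
|loading| made positive); standardization is within-cohort by default with
a global option.

## Enrichment

Selected sites (nonzero coefficient in ≥1 class) are tested against the
model's full training background with Fisher's exact test (two-sided, sum of
no-more-probable tables; the upper tail is also reported) for: SNP-probe
class, SNP-in-probe, mQTL membership, each chromosome vs rest, and each
CpG-island relation vs rest. The background includes the SNP probes. No
multiple-testing correction gates the 0.05 significance flag, but a
Benjamini–Hochberg column is emitted for transparency.

## Synthetic data generator

The generator produces multi-cohort beta matrices with known truth, under a
genetic architecture in which ancestry information enters methylation
measurements three ways:

* **SNP probes** (default 59): Balding–Nichols allele frequencies — per
  variant an ancestral frequency p ~ U(0.1, 0.9), per population a
  Beta(p(1−F)/F, (1−p)(1−F)/F) draw, F = FST = 0.15 by default; per sample
  genotype g ~ Binomial(2, q·p_pop) where q is the admixture vector; beta =
  clip(N(μ_g, 0.03²)) with trimodal means (0.05, 0.5, 0.95).
* **mQTL CpGs** (default 200): beta = logistic(logit(μ) + g·δ + batch +
  noise), where δ is the per-site logit shift that moves the mean by 0.15
  (beta scale) per alternate allele.
* **Background CpGs** (default 5000): site means from the standard
  hypo/hemi/hyper beta mixture, plus batch and noise on the logit scale.

Admixed samples (default 10%) draw q from a flat Dirichlet; pure samples
are one-hot with population weights (0.25, 0.25, 0.50). Cohort batch
effects are per-site N(0, 0.3) logit offsets shared within a cohort;
measurement noise is N(0, 0.05) on the logit scale; non-variable sites use
noise SD 0.005 and no batch term. Sex-chromosome sites use chrY means
0.8 (M) / 0.1 (F) and chrX 0.8 (M) / 0.5 (F). Planted defects: sites with
>1% failing detections or bead counts, isolated sub-threshold failures
(masked then imputed), uniform-noise samples, and reported-sex flips — all
recorded in the truth tables so QC bookkeeping is testable exactly. The
truth label uses the same 0.75 rule as the classifier (argmax of q, or
Mixed below 0.75), making "Ambiguous ⇔ Mixed" a testable correspondence.

Default cohort layout is 5 cohorts × 30 samples, a desk-scale study that a
full LODOCV sweep completes in about two minutes per seed; the bundled
study config tunes over a reduced grid (α ∈ {0.1, 0.5}, λ ∈ {0.003, 0.03,
0.25}, 3-fold, 1 repeat). The full 6 × 8 log-spaced grid over α ∈
[0.025, 0.5], λ ∈ [0.0025, 0.25] with 3 × 5-fold tuning remains the
default `HyperparameterGrid` for real-scale use.

What the generator does **not** emulate: linkage disequilibrium between
variants, probe-chemistry differences beyond the design-type shift,
cell-composition heterogeneity, age or disease covariate structure beyond
the nuisance columns, and realistic genome-wide correlation structure.
Passing the synthetic parameter-recovery suite therefore shows the pipeline
is correct and well-calibrated under the stated architecture, not that the
reported numbers transfer to any particular real cohort.

## Numerical choices and degenerate inputs

* FISTA step from the exact largest Gram eigenvalue; monotone restart; the
  λ = 0 case runs the same solver without thresholding.
* Singleton classes warn rather than error (the intercept-only limit is
  still well-defined); a single represented class errors.
* Probability ties in calls break by fixed class order (African < Asian <
  Caucasian) and are logged.
* Beta-mixture EM clamps component variances to the feasible (0, m(1−m))
  range and shape parameters to ≥0.05; values are clipped to
  [1e−6, 1−1e−6] before likelihood evaluation.
* Constant sites are dropped before standardization/PCA with a warning;
  constant covariates report R² = 0 with a note; PCA components clamp to
  the matrix rank.
* Fisher tests with a zero margin return p = 1 and an undefined (NaN) odds
  ratio; McNemar with no discordant pairs returns p = 1.

## Known limitations

* The three-class scheme inherits the coarseness of self-reported
  ethnicity; probabilities correlate with admixture but are not calibrated
  ancestry coefficients.
* BMIQ here is the mixture-CDF variant; implementations that map only the
  outer states and dilate the middle state will differ in the tails.
* The inter-array filter's 20% cap trades completeness for safety on small
  cohorts; a cohort that genuinely correlates poorly is reported, not fixed.
* LODOCV requires every training split to retain ≥ cv_folds samples per
  class; very small or single-class cohorts need fewer folds.
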