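# Methods

## Problem and model

A kidney allograft biopsy can be histologically stable (hSTA) while its
transcriptome resembles acute rejection (AR). The pipeline treats this as a
supervised-then-transfer problem: learn a discriminant between AR and
normal (pre-implantation) tissue on a merged multi-study cohort, compress
it into a linear score over a handful of z-scaled features, and apply that
score — with the z-scaling frozen on the AR+normal reference population —
to hSTA biopsies. A positive score labels the graft molecular rejection
(hSTA/mAR); zero or below labels it molecularly stable (hSTA/mSTA). An
exact zero maps to mSTA: strictly positive evidence is required to call
rejection.

The score is the linear predictor of an unpenalized logistic regression,
`score = β₀ + Σ β_f z_f`. The locked published model carries 6 gene
features and 5 cell-type-enrichment features; it ships as a versioned JSON
data file and is never recomputed by the package.

## Stages and their assumptions

**Quantile normalization** forces every sample onto the common reference
distribution (row means of column-sorted values). Ties receive the mean of
the reference values at their tied ranks, which makes the map deterministic
and idempotent. Missing values are rejected, not imputed: the synthetic
pathway never produces them, and silent imputation hides bugs.

**Probe collapse** keeps, per gene, the probe with the highest mean
intensity; mean/median aggregation is available behind a switch. The
max-mean rule favours the best-hybridizing probe and is the convention the
merged-microarray literature most often applies.

**Batch adjustment** is the parametric empirical-Bayes location-scale
model: standardize each gene with the batch-size-weighted grand mean and
pooled variance; estimate per-batch per-gene location (γ) and scale (δ)
effects; shrink γ toward a per-batch normal prior and δ toward a per-batch
inverse-gamma prior (method-of-moments hyperparameters) via the standard
iterative solution (convergence 1e-4); adjust and back-transform. The
implementation agrees with Bioconductor's reference implementation to
better than 1e-3 on random location-scale data (asserted in the test
suite). Two deliberate deviations handle degenerate input the reference
rejects: genes constant within some batch get an *unshrunk location-only*
adjustment (their batch mean removed exactly, no scale step), and a single
batch is the identity. No covariates are used in the batch design by
default; the scientific labels enter only downstream. Note that EB
shrinkage moves gene grand means by ~1e-3 even with equal batch sizes;
exact grand-mean preservation is not a property of this model and is tested
only at a 0.05 log2-unit tolerance.

**Differential expression** uses the moderated statistic
`d = Δmean / (s + s0)` with the pooled (not Welch) standard error, per the
original formulation. `s0` is chosen automatically as the percentile of the
per-gene standard errors (grid 0, 5, …, 100) minimizing the coefficient of
variation of |d| across genes. The permutation null permutes class labels
(exhaustively when the design admits fewer distinct assignments than
requested permutations) and pools |d*| across genes, giving p-value
resolution 1/(n_perm·n_genes) at small n_perm; a per-gene mode exists
behind a flag. BH adjustment is computed in-package with the classic
step-up arithmetic (q = p·n/k, running minimum) so it agrees exactly with a
brute-force oracle. Genes pass at adjusted p < 0.05 and |log2FC| >
log2 1.5, fold change being the difference of class means on the log2
scale. Class separation on the significant genes is tested by Ward
clustering cut at two clusters, with the adjusted Rand index against the
labels as statistic and a label-permutation null (the clustering itself is
label-blind, so only the ARI is recomputed per permutation).

**Cell-type enrichment** uses plain single-sample GSEA on user-supplied
GMT signatures rather than a calibrated multi-signature ensemble tool such
as xCell: per sample, genes are ranked (average ranks on ties, tie order
fixed by gene position), and the score is the mean gap between the
weighted (rank^0.25) cumulative in-set mass and the uniform out-of-set
mass, normalized by the universe size. Downstream stages consume only the
per-sample scores, which this statistic provides without spillover
compensation or platform calibration; the signature ensemble is therefore
the user's responsibility. AR-vs-normal testing is a two-sided rank-sum
test with BH correction; constant rows are flagged degenerate with p = 1.

**Feature selection** first drops features whose point-biserial |r| with
the outcome is ≤ 0.75·max|r| (constant features get r = 0), always keeping
the best feature. Recursive feature elimination then refits a random
forest per stratified CV fold (folds are stratified because class
imbalance across folds breaks AUROC estimation), ranks features by
impurity importance, and evaluates every candidate subset size by refitting
on the top-ranked subset and scoring held-out AUROC. The tolerance rule
picks the smallest size whose mean AUROC ≥ (1 − tol)·best, tol = 0.01 by
default. Forest seeds derive deterministically from the master seed by
repeat and fold index. The default candidate grid is {1..10, 15, 20, 30,
50, all}; the pipeline clips a user grid to the number of features
surviving the filter. Library defaults use 500 trees; the bundled tests
and examples use 30–100 trees and 2–10 repeats, which on cohorts of a few
hundred samples give the same chosen sizes as larger settings at a fraction
of the cost.

**Scoring and reclassification.** The z-scaler (mean/SD with denominator
n−1) is fit on the AR+normal reference cohort — never on hSTA samples,
whose deviation from that reference is exactly the signal being measured.
Whether the reference is all AR+normal samples or only the 80% training
split is configurable (`scaler_scope`); the default uses all, matching the
use of the score as a population-level instrument. Perfect separation in
the logistic fit (diverging MLE) triggers a logged refit with a small ridge
penalty (1e-4).

**Clinical validation** reports Pearson r (Spearman by flag) between score
and delta eGFR, the point-biserial r with graft loss, a Mann-Whitney
comparison of delta eGFR between predicted subphenotypes, and a separating
delta-eGFR threshold estimated as the cut maximizing Youden's J for
discriminating the predicted groups. The threshold estimator is a
surrogate — there is no canonical estimator for such a cut — and is
labelled as such in the output. The sign convention —
negative r means higher scores accompany greater eGFR decline — is stated
in the report rather than silently normalized.

## The synthetic cohort generator

The generator emulates, on the log2 scale,
`X[g,s] = μ_g + m_s·β_g + c·a[ct(g),s] + γ[b(s),g] + δ[b(s),g]·ε`, with
baseline means N(7, 1.5) (typical log2 microarray intensity), planted
effects β on `n_deg` genes (signed, mean magnitude `log2fc_effect`, planted
outside the signature genes so the two mechanisms stay separable), latent
instability m ∈ {0, attenuation, 1} for normal-like, hidden-mAR and AR
samples, latent cell-type activations raised by m for the five score cell
types (decoy signatures fluctuate around baseline), and per-study additive
offsets plus gene-wise scale factors matching the location-scale batch
model. The hidden state of each hSTA sample is Bernoulli(f_mar), f_mar =
0.46 by default — the reclassification fraction reported for the real
cohort. Default per-study class counts (18/22/41 over 28 studies) total
504/616/1148, mirroring the 510/609/1154 composition of the real
meta-cohort; tests use smaller cohorts.

Follow-up delta eGFR is `intercept + slope·m + noise` with defaults slope
−20 mL/min/1.73m² and noise SD 17, calibrated once so that the correlation
between latent state and delta eGFR is ≈ 0.5 in magnitude for a mixed hSTA
cohort (with m Bernoulli(0.46), sd ≈ 0.498, |r| = 20·0.498/√(20²·0.248 +
17²) ≈ 0.5), and group centers 0 vs −20 so the separating threshold falls
near the middle of that range. Graft loss is Bernoulli with log-odds
−2.9 + 1.5·m (≈5% baseline, ≈19% in rejection-like grafts), which at n=67
yields weak positive score correlations of the size seen in small clinical
cohorts. Latent instability is the generator's own attenuation multiplier,
*not* the downstream score — generation stays independent of inference.

What the generator does **not** emulate: probe-level platform structure,
background-correction artifacts, donor-specific antibody or histology
covariates, dependence between genes beyond the planted effects and
cell-type blocks, and non-Gaussian heavy tails. Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
model, not performance on real microarray data.

## Numerical choices and degenerate inputs

- Quantile normalization is exactly idempotent; the two-sample minimum is
  enforced.
- Permutation p-values use the (1 + exceedances)/(1 + draws) convention, so
  they are never zero.
- Ward clustering uses Euclidean distance; two-cluster tie-breaks are the
  deterministic order produced by the linkage, with sample order fixed.
- The correlation filter treats constant features as r = 0 and logs them.
- `reclassify_hsta` refuses cohorts with no hSTA samples; `apply_instascore`
  refuses missing model features rather than zero-filling.
- All generators and the pipeline are pure functions of (config, seed);
  repeated runs are bit-identical (asserted for matrices, score tables and
  written artifacts).

## Problem sizes used by the bundled checks

Unit tests run on matrices of 10–500 genes and tens of samples. The
statistical acceptance checks use: 100 null cohorts of 500 genes × 40
samples for false-discovery control; 200 seeds for p-value uniformity; 20
seeds of a 300-sample, 206-feature recovery problem for RFE (repeats = 10,
50 trees); n = 50 000 for logistic-coefficient consistency; and 20 seeds of
a 2-study cohort with 1000 genes and 1154 hSTA samples (150 AR/normal
reference samples) for end-to-end recovery of the planted 0.46 hidden-mAR
fraction. These sizes were chosen as the smallest at which the targeted
effects are comfortably identified.

## Known limitations

- Nonparametric empirical-Bayes priors for the batch model are not
  implemented (parametric priors only).
- The enrichment scorer does not compensate signature spillover between
  related cell types; correlated signatures yield correlated scores.
- The RFE importance ranking uses impurity importances, which are biased
  toward high-cardinality features; with standardized expression features
  this is benign, but mixed-type feature tables should prefer permutation
  importances (not implemented).
- Graft-loss association is a correlation, not a time-to-event analysis.
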