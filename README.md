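# instascore

Molecular reclassification of histologically stable kidney allografts.

Protocol biopsies of kidney transplants are routinely read by pathologists
as "stable" (hSTA), yet a substantial fraction of such grafts carry a
transcriptional signature indistinguishable from acute rejection (AR) and
go on to lose function. `instascore` implements the full analysis pipeline
that exposes this hidden heterogeneity in merged multi-study bulk
transcriptomic cohorts:

1. **Normalization & merging** — quantile normalization, probe-to-gene
   collapse, and empirical-Bayes location-scale batch adjustment (ComBat)
   across studies.
2. **Differential expression** — a SAM-style moderated statistic
   `d_g = (x̄_AR − x̄_N) / (s_g + s0)` with a permutation null pooled across
   genes, Benjamini-Hochberg correction, and a fold-change filter
   (adjusted p < 0.05, |log2FC| > log2 1.5), plus a Ward-clustering
   class-separation permutation test.
3. **Cell-type enrichment** — rank-based single-sample gene-set enrichment
   (ssGSEA, exponent α = 0.25) over user-supplied immune signatures (GMT),
   with Mann-Whitney AR-vs-normal testing.
4. **Feature selection** — point-biserial correlation filtering
   (|r| > 0.75·max|r|) followed by random-forest recursive feature
   elimination under repeated stratified 5-fold cross-validation, choosing
   the smallest feature set whose mean AUROC is within 1% of the best
   ("tolerance rule").
5. **The instability score** — logistic regression of AR vs normal on
   z-scaled selected features; the linear predictor

   `score(s) = β₀ + Σ_f β_f · z_f(s)`

   is the score. hSTA samples are reclassified at the zero threshold:
   score > 0 → molecular rejection (hSTA/mAR), score ≤ 0 → molecular
   stability (hSTA/mSTA). The published, locked 11-feature model
   (genes *KLF4, CENPJ, KLF2, PPP1R15A, FOSB, TNFAIP3*; cell types NK,
   CD4 Tcm, CD4 Tem, CD8 Tem, Th1) ships with the package.
6. **Clinical validation** — Pearson association of scores with
   follow-up delta eGFR and graft-loss events, Mann-Whitney comparison of
   delta eGFR between predicted subphenotypes, and a Youden-optimal
   separating delta-eGFR threshold.

Because the original 28-study GEO cohort (2273 biopsies) cannot be bundled,
a first-class synthetic-data module generates multi-study cohorts with the
same statistical structure — planted differential genes, latent immune-cell
abundances expressed through signature genes, per-study location-scale
batch effects, an hSTA population that hides a 46% rejection-like mixture,
and follow-up eGFR correlated with the latent state at |r| ≈ 0.5 — so every
stage is testable end to end against a known truth.

## Worked example

```python
import pandas as pd
from instascore import ZScaler, apply_instascore, load_locked_model

model = load_locked_model()                 # the published coefficients
scaler = ZScaler.identity(model.features)   # features already z-scaled
biopsy = pd.DataFrame([{f: 0.0 for f in model.features}], index=["b1"])
biopsy["NK cells"] = 1.0                    # one z-unit of NK enrichment
print(apply_instascore(model, scaler, biopsy).iloc[0])
```

prints `2.845` = 0.596 (intercept) + 2.249 (NK-cell coefficient): a graft
one standard deviation above the reference cohort in NK-cell enrichment
already scores positive, i.e. on the molecular-rejection side of the zero
threshold.

Refitting the score on a simulated cohort and recovering the planted
hidden-rejection fraction (`python examples/06_instascore_reclassification.py`):

```
locked score at all-zero z-features: 0.596
one z-unit of NK-cell enrichment adds 2.249 score units

selected features: ['CD8 Tem', 'CD4 Tem', 'CD4 Tcm', 'NK cells']
test AUROC (AR vs normal): 1.000
estimated mAR fraction among hSTA: 0.430 (planted truth 0.430)
```

The estimated molecular-rejection fraction among hSTA grafts matches the
fraction planted by the generator. The other `examples/*.py` scripts walk
through each stage (simulation, preprocessing, differential expression,
enrichment, feature selection, clinical validation) in the same style, and
the `instascore` console script chains them from the shell
(`instascore run --seed 1 --outdir run/`).

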