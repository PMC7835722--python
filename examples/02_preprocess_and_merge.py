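"""Quantile-normalize and batch-adjust a merged multi-study matrix.

Shows that per-study location shifts visible in the raw merge disappear
after the empirical-Bayes adjustment, while sample-level structure remains.
"""

import numpy as np

from instascore import (
    CohortConfig, combat_adjust, gene_universe, generate_cohort,
    generate_signatures, quantile_normalize,
)

universe = gene_universe(500)
sigs = generate_signatures(8, 15, universe, seed=2)
cfg = CohortConfig(
    n_studies=3, samples_per_study={"AR": 10, "normal": 10, "hSTA": 10},
    n_genes=500, n_deg=40, batch_shift_sd=1.0, seed=2,
)
expr, samples = generate_cohort(cfg, sigs)


def between_study_gap(X):
    means = X.T.groupby(samples["study_id"]).mean()
    return float((means.max(axis=0) - means.min(axis=0)).mean())


X = quantile_normalize(expr)
print(f"mean between-study gene-mean gap before adjustment: {between_study_gap(X):.3f}")
X_adj = combat_adjust(X, samples)
print(f"mean between-study gene-mean gap after adjustment:  {between_study_gap(X_adj):.3f}")
print(f"dimensions preserved: {X_adj.shape == expr.shape}")
# The gap shrinks by roughly an order of magnitude: the per-study additive
# offsets (batch_shift_sd=1.0) are absorbed by the location-scale model.
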