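"""Simulate a multi-study kidney-transplant expression cohort.

Builds a small three-study cohort with planted rejection genes, latent
immune-cell signal, per-study batch effects, and an hSTA population that
secretly mixes normal-like and rejection-like grafts (46% hidden mAR).
"""

from instascore import CohortConfig, gene_universe, generate_cohort, generate_signatures

universe = gene_universe(800)
signatures = generate_signatures(n_celltypes=10, genes_per_set=20, universe=universe, seed=1)

config = CohortConfig(
    n_studies=3,
    samples_per_study={"AR": 15, "normal": 15, "hSTA": 30},
    n_genes=800,
    n_deg=60,
    seed=1,
)
expr, samples = generate_cohort(config, signatures)

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(samples["diagnosis"].value_counts().to_string())
hidden = samples.query("diagnosis == 'hSTA'")["hidden_state"].value_counts(normalize=True)
print(f"\nhidden state of the hSTA samples (truth the pipeline must recover):")
print(hidden.to_string())
# The AR-like fraction fluctuates binomially around the configured f_mar=0.46.
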