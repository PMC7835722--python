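{
  "name": "locked-instascore-v1",
  "intercept": 0.596,
  "coefficients": {
    "KLF4": 2.096,
    "CENPJ": 2.534,
    "KLF2": 0.311,
    "PPP1R15A": 1.447,
    "FOSB": -1.633,
    "TNFAIP3": 0.268,
    "NK cells": 2.249,
    "CD4 Tcm": 0.542,
    "CD4 Tem": 0.833,
    "CD8 Tem": 0.709,
    "Th1": 0.146
  },
  "gene_features": ["KLF4", "CENPJ", "KLF2", "PPP1R15A", "FOSB", "TNFAIP3"],
  "celltype_features": ["NK cells", "CD4 Tcm", "CD4 Tem", "CD8 Tem", "Th1"]
}
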