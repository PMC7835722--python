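import numpy as np
import pandas as pd
import pytest

from instascore import CohortConfig, gene_universe, generate_cohort, generate_signatures


@pytest.fixture(scope="session")
def small_cohort():
    """One small multi-study cohort shared by read-only tests."""
    universe = gene_universe(400)
    sigs = generate_signatures(8, 15, universe, seed=11)
    cfg = CohortConfig(
        n_studies=3,
        samples_per_study={"AR": 12, "normal": 12, "hSTA": 20},
        n_genes=400,
        n_deg=40,
        seed=11,
    )
    expr, samples = generate_cohort(cfg, sigs)
    return {"config": cfg, "signatures": sigs, "expr": expr, "samples": samples}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_feature_with_r(y: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Feature whose empirical point-biserial correlation with y is exactly r
    (construct via Gram-Schmidt: r * unit(y - mean) + sqrt(1-r^2) * orthonormal noise)."""
    z = y - y.mean()
    z = z / np.linalg.norm(z)
    u = rng.standard_normal(len(y))
    u = u - u.mean()
    u = u - (u @ z) * z
    u = u / np.linalg.norm(u)
    return r * z + np.sqrt(1 - r**2) * u
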