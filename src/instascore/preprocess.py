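"""Normalization and multi-study merging of expression matrices.

The fixed pipeline order for merging microarray studies is: log2 transform
(if the input is detected or declared linear-scale), quantile normalization,
probe-to-gene collapse, merge, then empirical-Bayes location-scale batch
adjustment (ComBat).  Missing values are rejected rather than imputed.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "log2_if_needed",
    "quantile_normalize",
    "collapse_probes",
    "combat_adjust",
]


def log2_if_needed(X: pd.DataFrame, linear: bool | None = None) -> pd.DataFrame:
    """log2(x+1)-transform a matrix that is on the linear intensity scale.

    With ``linear=None`` the scale is guessed: intensities whose maximum
    exceeds 50 are taken to be linear (log2 microarray data rarely exceeds
    ~16).  Pass ``linear=True``/``False`` to override the guess.
    """
    if linear is None:
        linear = float(np.nanmax(X.to_numpy())) > 50.0
        logger.info("scale detection: treating input as %s-scale", "linear" if linear else "log")
    if not linear:
        return X
    if (X.to_numpy() < 0).any():
        raise ValueError("negative intensities cannot be on the linear scale")
    return np.log2(X + 1.0)


def quantile_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto a common intensity distribution.

    The reference distribution is the vector of row means of the
    column-sorted matrix; each column's values are replaced by the reference
    values at their within-column ranks.  Tied values within a column
    receive the mean of the reference values at their tied ranks, which
    makes the operation deterministic and idempotent.
    """
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = X.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError("quantile normalization does not accept missing/non-finite values")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference over each tied block of the sorted column
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col_sorted)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def collapse_probes(
    X: pd.DataFrame, probe_map: Mapping[str, str], rule: str = "max_mean"
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene symbol.

    Probes absent from ``probe_map`` are dropped (with a logged count).
    Under the default ``max_mean`` rule the probe with the highest mean
    intensity across samples represents its gene; ``mean`` and ``median``
    aggregate all probes of a gene instead.
    """
    mapped = X.index.to_series().map(dict(probe_map))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not keep.any():
        raise ValueError("no probe in the matrix maps to a gene symbol")
    sub = X.loc[keep]
    genes = mapped[keep]
    if rule == "max_mean":
        probe_means = sub.mean(axis=1)
        best = probe_means.groupby(genes.values, sort=True).idxmax()
        out = sub.loc[best.values]
        out.index = pd.Index(best.index, name="gene")
    elif rule in ("mean", "median"):
        out = sub.groupby(genes.values, sort=True).agg(rule)
        out.index.name = "gene"
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    return out


def combat_adjust(
    X: pd.DataFrame, batches: pd.Series | pd.DataFrame, parametric: bool = True
) -> pd.DataFrame:
    """Empirical-Bayes location-scale batch adjustment of a merged matrix.

    Implements the standard parametric adjustment: genes are standardized
    against the batch-size-weighted grand mean and pooled variance; per-batch
    per-gene location (gamma) and scale (delta) effects are estimated and
    shrunk toward batch-level priors (normal prior on gamma, inverse-gamma
    prior on delta, hyperparameters by method of moments) via the usual
    iterative EB solution; data are adjusted and back-transformed.  Genes
    that are constant within some batch fall back to location-only
    adjustment (no scale shrinkage), logged per gene.

    ``batches`` is either a Series of batch labels indexed by sample id or a
    sample table with a ``study_id`` column.
    """
    if not parametric:
        raise NotImplementedError("nonparametric priors are not provided")
    if isinstance(batches, pd.DataFrame):
        batches = batches["study_id"]
    batch = batches.reindex(X.columns)
    if batch.isna().any():
        missing = list(X.columns[batch.isna()])[:5]
        raise ValueError(f"samples without batch label, e.g. {missing}")
    values = X.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError("batch adjustment does not accept missing/non-finite values")

    levels = pd.Categorical(batch)
    codes = levels.codes
    names = list(levels.categories)
    n_batches = len(names)
    counts = np.bincount(codes, minlength=n_batches)
    small = [names[b] for b in range(n_batches) if counts[b] < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if n_batches == 1:
        logger.info("combat_adjust: single batch, adjustment is the identity")
        return X.copy()

    G, N = values.shape
    # per-batch gene means and the batch-size-weighted grand mean
    batch_means = np.stack([values[:, codes == b].mean(axis=1) for b in range(n_batches)])
    grand_mean = (counts / N) @ batch_means
    resid = values - batch_means[codes].T
    var_pooled = (resid**2).sum(axis=1) / N
    zero_var = var_pooled <= 0
    if zero_var.any():
        # within-batch-constant genes: standardize with unit scale; they fall
        # into the location-only path below and have their offsets removed
        logger.info("combat_adjust: %d genes with zero pooled variance", int(zero_var.sum()))
        var_pooled = np.where(zero_var, 1.0, var_pooled)

    sd = np.sqrt(var_pooled)
    Z = (values - grand_mean[:, None]) / sd[:, None]

    gamma_hat = np.stack([Z[:, codes == b].mean(axis=1) for b in range(n_batches)])
    delta_hat = np.stack([Z[:, codes == b].var(axis=1, ddof=1) for b in range(n_batches)])

    location_only = (delta_hat <= 0).any(axis=0)
    if location_only.any():
        logger.info(
            "combat_adjust: %d genes constant within a batch; location-only adjustment",
            int(location_only.sum()),
        )

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)

    # degenerate genes get an unshrunk location-only adjustment; the EB
    # machinery (prior moments and iterations) runs on the clean genes only
    gamma_star = gamma_hat.copy()
    delta_star = np.ones_like(delta_hat)
    ok = ~location_only
    if ok.sum() >= 2:
        for b in range(n_batches):
            m = delta_hat[b, ok].mean()
            s2 = delta_hat[b, ok].var(ddof=1)
            if s2 <= 0:
                continue  # flat scale estimates: nothing to shrink toward
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            Zb = Z[np.ix_(ok, codes == b)]
            n_b = counts[b]
            g_hat = gamma_hat[b, ok]
            g_old = g_hat.copy()
            d_old = delta_hat[b, ok].copy()
            for _ in range(500):
                g_new = (tau2[b] * n_b * g_hat + d_old * gamma_bar[b]) / (
                    tau2[b] * n_b + d_old
                )
                sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                    np.max(np.abs(d_new - d_old) / d_old),
                )
                g_old, d_old = g_new, d_new
                if change < 1e-4:
                    break
            gamma_star[b, ok] = g_old
            delta_star[b, ok] = d_old
    Z_adj = np.empty_like(Z)
    for b in range(n_batches):
        sel = codes == b
        Z_adj[:, sel] = (Z[:, sel] - gamma_star[b][:, None]) / np.sqrt(delta_star[b])[:, None]
    out = Z_adj * sd[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=X.index, columns=X.columns)
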