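"""Single-sample gene-set enrichment for cell-type scoring.

Each signature (a list of marker genes for one cell type) is scored per
sample with the rank-based single-sample running-sum statistic: genes are
ordered by decreasing expression within the sample, and the score is the
average gap between the weighted cumulative fraction of in-set genes (rank
weights raised to an exponent ``alpha``) and the cumulative fraction of
out-of-set genes.  Scores depend only on within-sample ranks, so they are
invariant to monotone transforms of a sample's expression and comparable
across heterogeneous platforms.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .diffexp import bh_adjust, _binary_masks

logger = logging.getLogger(__name__)

__all__ = ["ssgsea_scores", "enrichment_diff_test"]


def ssgsea_scores(
    X: pd.DataFrame, sets: Mapping[str, list[str]], alpha: float = 0.25, min_overlap: int = 3
) -> pd.DataFrame:
    """Cell-type-by-sample enrichment score matrix.

    Ties in expression get average ranks (and a deterministic ordering by
    gene position), so the scores are invariant to gene order and to sample
    permutations.  Sets overlapping the matrix by fewer than ``min_overlap``
    genes are dropped with a warning; genes absent from the matrix are
    ignored and do not change a set's score.
    """
    gene_pos = {g: i for i, g in enumerate(X.index)}
    members: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        rows = np.array(sorted({gene_pos[g] for g in genes if g in gene_pos}), dtype=int)
        if len(rows) < min_overlap:
            logger.warning(
                "ssgsea: set %r overlaps matrix by %d genes (<%d); dropped",
                name, len(rows), min_overlap,
            )
            continue
        members[name] = rows
    if not members:
        raise ValueError("no gene set overlaps the expression matrix")

    values = X.to_numpy(float)
    G, n_samples = values.shape
    scores = np.zeros((len(members), n_samples))
    names = list(members)
    member_masks = np.zeros((len(names), G), dtype=bool)
    for i, name in enumerate(names):
        member_masks[i, members[name]] = True

    for j in range(n_samples):
        col = values[:, j]
        ranks = rankdata(col, method="average")
        # descending expression; ties broken by gene position for determinism
        order = np.lexsort((np.arange(G), -ranks))
        w_ordered = ranks[order] ** alpha
        for i in range(len(names)):
            in_mask = member_masks[i][order]
            n_in = in_mask.sum()
            w_in = np.where(in_mask, w_ordered, 0.0)
            cum_in = np.cumsum(w_in) / w_in.sum()
            cum_out = np.cumsum(~in_mask) / (G - n_in)
            scores[i, j] = (cum_in - cum_out).sum() / G
    return pd.DataFrame(scores, index=pd.Index(names, name="cell_type"), columns=X.columns)


def enrichment_diff_test(E: pd.DataFrame, labels, positive=None) -> pd.DataFrame:
    """Per-cell-type two-sided Mann-Whitney test between the two classes.

    Returns a table with the U statistic, raw and BH-adjusted p-values, the
    direction of the shift (sign of the median difference, ``up`` = higher
    in the positive class), a significance flag at adjusted p < 0.05, and a
    ``degenerate`` flag for constant score rows (reported with p = 1).
    """
    pos, neg, _ = _binary_masks(labels, positive)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be non-empty")
    rows = []
    for name, row in E.iterrows():
        a = row.to_numpy(float)[pos]
        b = row.to_numpy(float)[neg]
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((name, np.nan, 1.0, 0.0, True))
            continue
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((name, stat, p, np.median(a) - np.median(b), False))
    out = pd.DataFrame(
        rows, columns=["cell_type", "U", "p", "median_diff", "degenerate"]
    ).set_index("cell_type")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["median_diff"] > 0, "up", "down")
    out["significant"] = out["adj_p"] < 0.05
    return out
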