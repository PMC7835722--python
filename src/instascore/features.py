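"""Feature reduction for the rejection classifier.

Two stages mirror the published procedure: an outcome-correlation filter
(keep features whose point-biserial |r| exceeds 0.75 of the best feature's
|r|), then recursive feature elimination with a random forest under
repeated stratified cross-validation, picking the smallest candidate size
whose mean held-out AUROC is within a 1% tolerance of the best size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_filter",
    "rfe_select",
    "benchmark_model",
    "split_train_test",
    "SelectionResult",
    "default_sizes",
]


def split_train_test(
    F: pd.DataFrame, y: np.ndarray, test_size: float = 0.2, seed: int = 0, groups=None
):
    """Stratified 80:20 split of a sample-by-feature table.

    With ``groups`` (e.g. study ids) the stratification is on the
    label-group combination so every study contributes to both halves.
    """
    y = np.asarray(y)
    strat = y if groups is None else np.char.add(y.astype(str), np.asarray(groups).astype(str))
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_size, random_state=seed, stratify=strat
    )
    return F.iloc[idx_train], y[idx_train], F.iloc[idx_test], y[idx_test]


def correlation_filter(F: pd.DataFrame, y, frac: float = 0.75) -> list[str]:
    """Keep features whose point-biserial |r| with the outcome exceeds
    ``frac`` times the maximum |r|; the best feature is always retained.

    Constant features get r = 0 (logged) and can never pass.
    """
    if F.shape[1] < 2:
        if F.shape[1] == 1:
            return list(F.columns)
        raise ValueError("no features to filter")
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    values = F.to_numpy(float)
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("correlation_filter: %d constant features get r=0", int(constant.sum()))
    yc = y - y.mean()
    r = np.zeros(F.shape[1])
    ok = ~constant
    cov = (values[:, ok] - values[:, ok].mean(axis=0)).T @ yc / len(y)
    r[ok] = np.abs(cov / (sd[ok] * y.std()))
    best = int(np.argmax(r))
    keep = r > frac * r[best]
    keep[best] = True
    return [c for c, k in zip(F.columns, keep) if k]


def default_sizes(n_features: int) -> list[int]:
    sizes = sorted({s for s in [*range(1, 11), 15, 20, 30, 50, n_features] if s <= n_features})
    return sizes


@dataclass
class SelectionResult:
    """Outcome of the RFE + tolerance pick."""

    sizes: list[int]
    mean_auroc: dict[int, float]
    chosen_size: int
    features: list[str]
    tol: float
    metrics: dict = field(default_factory=dict)


def _rf(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def _rank_features(model: RandomForestClassifier) -> np.ndarray:
    """Indices ordered by decreasing impurity importance, ties by index."""
    imp = model.feature_importances_
    return np.lexsort((np.arange(len(imp)), -imp))


def pick_size_tolerance(sizes, mean_auroc: dict[int, float], tol: float) -> int:
    """Smallest candidate size whose mean CV AUROC is within ``tol`` of the
    best size's (>= (1-tol) * max); at tol=0 this is the argmax with ties
    going to the smaller size."""
    best = max(mean_auroc.values())
    for s in sorted(sizes):
        if mean_auroc[s] >= (1.0 - tol) * best:
            return s
    raise RuntimeError("tolerance pick found no qualifying size")  # pragma: no cover


def rfe_select(
    F_train: pd.DataFrame,
    y_train,
    sizes: list[int] | None = None,
    k: int = 5,
    repeats: int = 100,
    tol: float = 0.01,
    seed: int = 0,
    n_estimators: int = 500,
) -> SelectionResult:
    """Recursive feature elimination with a random forest.

    For every repeat and stratified CV fold, a forest is fit on the fold's
    training split, features are ranked by impurity importance, and each
    candidate subset size is evaluated by refitting on the top-ranked
    subset and scoring held-out AUROC.  Mean AUROC per size over all
    repeat-fold pairs feeds the tolerance pick; the final feature names are
    the top-ranked features at the chosen size from a fit on the full
    training set.  All forest seeds derive deterministically from ``seed``
    via the repeat and fold index.
    """
    y = np.asarray(y_train)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary")
    n_features = F_train.shape[1]
    if sizes is None:
        sizes = default_sizes(n_features)
    sizes = sorted(set(sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > n_features:
        raise ValueError(f"candidate sizes must be within [1, {n_features}]")
    if min(np.bincount((y == np.unique(y)[1]).astype(int))) < k:
        raise ValueError("too few samples in a class for stratified folds")

    values = F_train.to_numpy(float)
    yb = (y == np.unique(y)[1]).astype(int) if y.dtype.kind not in "biu" else y.astype(int)
    aurocs = {s: [] for s in sizes}
    for rep in range(repeats):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed * 10007 + rep)
        for fold, (tr, te) in enumerate(cv.split(values, yb)):
            fold_seed = (seed * 1000003 + rep * 101 + fold) % (2**31 - 1)
            ranker = _rf(fold_seed, n_estimators).fit(values[tr], yb[tr])
            order = _rank_features(ranker)
            for s in sizes:
                cols = order[:s]
                clf = _rf(fold_seed, n_estimators).fit(values[tr][:, cols], yb[tr])
                prob = clf.predict_proba(values[te][:, cols])[:, 1]
                aurocs[s].append(roc_auc_score(yb[te], prob))
    mean_auroc = {s: float(np.mean(v)) for s, v in aurocs.items()}
    chosen = pick_size_tolerance(sizes, mean_auroc, tol)
    final = _rf(seed % (2**31 - 1), n_estimators).fit(values, yb)
    order = _rank_features(final)
    features = [F_train.columns[i] for i in order[:chosen]]
    return SelectionResult(
        sizes=sizes, mean_auroc=mean_auroc, chosen_size=chosen, features=features, tol=tol
    )


def benchmark_model(
    features: list[str],
    F_train: pd.DataFrame,
    y_train,
    F_test: pd.DataFrame,
    y_test,
    seed: int = 0,
    n_estimators: int = 500,
) -> dict:
    """Held-out performance of a random forest on the selected features.

    Reports test AUROC (trapezoidal over the empirical ROC), AUCPR
    (step-wise precision-recall integral), and sensitivity/specificity at a
    0.5 probability cutoff.
    """
    missing = [f for f in features if f not in F_train.columns]
    if missing:
        raise ValueError(f"selected features missing from the table: {missing}")
    y_tr = np.asarray(y_train).astype(int)
    y_te = np.asarray(y_test).astype(int)
    if len(np.unique(y_te)) < 2:
        raise ValueError("test set contains a single class; AUROC undefined")
    clf = _rf(seed % (2**31 - 1), n_estimators).fit(F_train[features].to_numpy(float), y_tr)
    prob = clf.predict_proba(F_test[features].to_numpy(float))[:, 1]
    pred = prob >= 0.5
    tp = int(((pred == 1) & (y_te == 1)).sum())
    tn = int(((pred == 0) & (y_te == 0)).sum())
    return {
        "auroc": float(roc_auc_score(y_te, prob)),
        "aucpr": float(average_precision_score(y_te, prob)),
        "sensitivity": tp / int((y_te == 1).sum()),
        "specificity": tn / int((y_te == 0).sum()),
    }
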