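"""The linear instability score over z-scaled features.

The score is the linear predictor of a logistic regression of acute
rejection (AR = 1) versus normal on z-scaled gene-expression and cell-type
enrichment features:

    score(s) = b0 + sum_f b_f * z_f(s)

Positive scores indicate molecular rejection; the decision threshold is
zero.  Histologically stable (hSTA) samples are reclassified by applying
the score with the z-scaling frozen on the AR+normal reference cohort:
score > 0 maps to hSTA/mAR (molecular rejection), score <= 0 to hSTA/mSTA
(molecular stability; an exact zero counts as stable).

The published, locked 11-feature model (6 genes, 5 cell types) ships with
the package and can be applied to any feature table carrying the same
feature names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "ZScaler",
    "ScoreModel",
    "load_locked_model",
    "fit_zscaler",
    "fit_score_model",
    "apply_instascore",
    "reclassify_hsta",
]


@dataclass
class ZScaler:
    """Per-feature reference mean and SD (fit on the AR+normal cohort)."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, F: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.mean.index if f not in F.columns]
        if missing:
            raise ValueError(f"feature table lacks scaled features: {missing}")
        sub = F[self.mean.index]
        return (sub - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {f: {"mean": float(self.mean[f]), "sd": float(self.sd[f])} for f in self.mean.index}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScaler":
        names = list(d)
        return cls(
            mean=pd.Series({f: d[f]["mean"] for f in names}),
            sd=pd.Series({f: d[f]["sd"] for f in names}),
        )

    @classmethod
    def identity(cls, features: list[str]) -> "ZScaler":
        """No-op scaler for inputs that are already z-scaled."""
        return cls(
            mean=pd.Series(0.0, index=pd.Index(features)),
            sd=pd.Series(1.0, index=pd.Index(features)),
        )


def fit_zscaler(F_ref: pd.DataFrame) -> ZScaler:
    """Fit per-feature mean/SD (denominator n-1) on a reference cohort."""
    if len(F_ref) < 2:
        raise ValueError("need at least 2 reference samples")
    sd = F_ref.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant features cannot be z-scaled: {list(constant.index)}")
    return ZScaler(mean=F_ref.mean(), sd=sd)


@dataclass
class ScoreModel:
    """Intercept + named coefficients of the linear score."""

    intercept: float
    coefficients: dict[str, float]
    gene_features: list[str] = field(default_factory=list)
    celltype_features: list[str] = field(default_factory=list)
    name: str = "refit"

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "gene_features": self.gene_features,
            "celltype_features": self.celltype_features,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ScoreModel":
        d = json.loads(source)
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            gene_features=list(d.get("gene_features", [])),
            celltype_features=list(d.get("celltype_features", [])),
            name=d.get("name", "refit"),
        )


def load_locked_model() -> ScoreModel:
    """The published 6-gene / 5-cell-type model with locked coefficients."""
    text = resources.files("instascore").joinpath("data/locked_model.json").read_text()
    return ScoreModel.from_json(text)


def fit_score_model(
    Z: pd.DataFrame,
    outcome,
    gene_features: list[str] | None = None,
    celltype_features: list[str] | None = None,
) -> ScoreModel:
    """Fit the score by unpenalized logistic regression on z-scaled features.

    The fitted intercept and coefficients become the linear score verbatim.
    If the classes are perfectly separated (the unpenalized MLE diverges),
    the model is refit with a small ridge penalty (1e-4) and this is logged.
    """
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    Xv = Z.to_numpy(float)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(Xv, y)
    margins = (2 * y - 1) * (clf.intercept_[0] + Xv @ clf.coef_[0])
    if (margins > 0).all() and np.abs(clf.coef_).max() > 30:
        logger.warning("fit_score_model: perfect separation; refitting with ridge penalty 1e-4")
        clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
        clf.fit(Xv, y)
    coefs = {f: float(c) for f, c in zip(Z.columns, clf.coef_[0])}
    return ScoreModel(
        intercept=float(clf.intercept_[0]),
        coefficients=coefs,
        gene_features=gene_features or [],
        celltype_features=celltype_features or [],
    )


def apply_instascore(model: ScoreModel, scaler: ZScaler, F: pd.DataFrame) -> pd.Series:
    """Evaluate the linear score on a feature table.

    ``F`` holds raw features (one row per sample); ``scaler`` carries the
    frozen reference z-scaling.  Every model feature must be present by
    name; extras are ignored with a log line, and missing features are an
    error (never silently zero-filled).
    """
    missing = [f for f in model.features if f not in F.columns]
    if missing:
        raise ValueError(f"feature table lacks model features: {missing}")
    extra = [f for f in F.columns if f not in model.features]
    if extra:
        logger.info("apply_instascore: ignoring %d extra features", len(extra))
    Z = scaler.transform(F[model.features])
    beta = np.array([model.coefficients[f] for f in model.features])
    scores = model.intercept + Z.to_numpy(float) @ beta
    return pd.Series(scores, index=F.index, name="instascore")


def reclassify_hsta(scores: pd.Series, samples: pd.DataFrame) -> tuple[pd.Series, float]:
    """Split hSTA samples into molecular rejection vs molecular stability.

    Returns per-sample labels (``hSTA/mAR`` for score > 0, ``hSTA/mSTA``
    for score <= 0; an exact zero is stable) and the mAR fraction.
    """
    hsta = samples.index[samples["diagnosis"] == "hSTA"]
    if len(hsta) == 0:
        raise ValueError("no hSTA samples to reclassify")
    missing = hsta.difference(scores.index)
    if len(missing):
        raise ValueError(f"scores missing for hSTA samples, e.g. {list(missing[:5])}")
    s = scores.loc[hsta]
    labels = pd.Series(
        np.where(s > 0, "hSTA/mAR", "hSTA/mSTA"), index=hsta, name="subphenotype"
    )
    return labels, float((s > 0).mean())
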