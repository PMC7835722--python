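"""End-to-end orchestration: simulate/load, normalize, test, select, score.

``run_refit_pipeline`` is the in-memory engine: given an expression matrix,
sample table and signature collection it rebuilds the instability score from
scratch (differential expression, cell-type enrichment, feature selection,
logistic fit) and reclassifies the hSTA samples.  ``run_pipeline`` wraps it
with file I/O, a resolved-config dump and a manifest so that identical
config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iom
from .diffexp import select_degs
from .enrichment import enrichment_diff_test, ssgsea_scores
from .features import (
    benchmark_model,
    correlation_filter,
    rfe_select,
    split_train_test,
)
from .preprocess import combat_adjust, quantile_normalize
from .score import (
    apply_instascore,
    fit_score_model,
    fit_zscaler,
    load_locked_model,
    reclassify_hsta,
)
from .synthdata import CohortConfig, generate_cohort, generate_followup, generate_signatures, gene_universe
from .validation import compare_subphenotypes, correlate_outcome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_refit_pipeline"]


@dataclass
class PipelineConfig:
    """Fully resolved pipeline settings; unknown keys are rejected."""

    # inputs: either simulate=True or paths to expression/samples/gmt
    simulate: bool = True
    expression: str | None = None
    samples: str | None = None
    gmt: str | None = None
    followup: str | None = None
    outdir: str = "instascore_run"
    # synthetic-cohort settings (used when simulate=True)
    n_studies: int = 4
    samples_per_study: dict = field(default_factory=lambda: {"AR": 20, "normal": 20, "hSTA": 40})
    n_genes: int = 1000
    n_deg: int = 80
    n_celltypes: int = 10
    genes_per_set: int = 20
    # stage parameters
    qn: bool = True
    combat: bool = True
    alpha: float = 0.05
    fc_thresh: float = 1.5
    n_perm: int = 200
    frac: float = 0.75
    folds: int = 5
    repeats: int = 5
    tol: float = 0.01
    sizes: list | None = None
    n_estimators: int = 100
    model: str = "refit"  # "refit" or "locked"
    scaler_scope: str = "all"  # "all" (AR+normal) or "train" (80% split only)
    group_by_study: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_refit_pipeline(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    signatures: dict,
    followup: pd.DataFrame | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Rebuild the instability score on a cohort and reclassify its hSTA
    samples; returns every intermediate result keyed by stage."""
    cfg = cfg or PipelineConfig()
    out: dict = {}

    X = expr
    if cfg.qn:
        X = quantile_normalize(X)
    if cfg.combat and samples["study_id"].nunique() > 1:
        X = combat_adjust(X, samples)
    out["expression"] = X

    ar_norm = samples.index[samples["diagnosis"].isin(["AR", "normal"])]
    labels = samples.loc[ar_norm, "diagnosis"]
    degs = select_degs(
        X[ar_norm], labels, n_perm=cfg.n_perm, alpha=cfg.alpha,
        fc_thresh=cfg.fc_thresh, seed=cfg.seed,
    )
    out["degs"] = degs
    logger.info("diffexp: %d DEGs (%d up, %d down)", len(degs),
                (degs["direction"] == "up").sum(), (degs["direction"] == "down").sum())

    E = ssgsea_scores(X, signatures)
    out["enrichment"] = E
    out["enrichment_test"] = enrichment_diff_test(E[ar_norm], labels)

    # feature table: DEG expression + cell-type scores, samples in rows
    F = pd.concat([X.loc[degs.index].T, E.T], axis=1)
    y = (samples["diagnosis"] == "AR").astype(int)
    F_ref, y_ref = F.loc[ar_norm], y.loc[ar_norm].to_numpy()
    groups = samples.loc[ar_norm, "study_id"] if cfg.group_by_study else None
    F_tr, y_tr, F_te, y_te = split_train_test(F_ref, y_ref, seed=cfg.seed, groups=groups)

    kept = correlation_filter(F_tr, y_tr, frac=cfg.frac)
    out["filtered_features"] = kept
    sizes = cfg.sizes
    if sizes is not None:
        sizes = sorted({min(s, len(kept)) for s in sizes})
    sel = rfe_select(
        F_tr[kept], y_tr, sizes=sizes, k=cfg.folds, repeats=cfg.repeats,
        tol=cfg.tol, seed=cfg.seed, n_estimators=cfg.n_estimators,
    )
    out["selection"] = sel
    sel.metrics = benchmark_model(
        sel.features, F_tr, y_tr, F_te, y_te, seed=cfg.seed, n_estimators=cfg.n_estimators
    )
    logger.info("selection: %d features, test AUROC %.3f", sel.chosen_size, sel.metrics["auroc"])

    if cfg.model == "locked":
        model = load_locked_model()
    else:
        ref_idx = F_tr.index if cfg.scaler_scope == "train" else F_ref.index
        scaler = fit_zscaler(F_ref.loc[ref_idx, sel.features])
        Z = scaler.transform(F_ref.loc[ref_idx])
        y_fit = y.loc[ref_idx].to_numpy()
        celltypes = [f for f in sel.features if f in E.index]
        model = fit_score_model(
            Z, y_fit,
            gene_features=[f for f in sel.features if f not in celltypes],
            celltype_features=celltypes,
        )
    if cfg.model == "locked":
        scaler = fit_zscaler(F_ref[[f for f in model.features if f in F_ref.columns]])
    out["scaler"] = scaler
    out["model"] = model

    scores = apply_instascore(model, scaler, F)
    out["scores"] = scores
    sub_labels, mar_fraction = reclassify_hsta(scores, samples)
    out["subphenotypes"] = sub_labels
    out["mar_fraction"] = mar_fraction
    logger.info("reclassification: mAR fraction %.3f among %d hSTA", mar_fraction, len(sub_labels))

    if followup is not None:
        hsta_scores = scores.loc[sub_labels.index]
        out["validation"] = {
            "correlation": correlate_outcome(hsta_scores, followup),
            "subphenotypes": compare_subphenotypes(followup, sub_labels),
        }
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """File-level pipeline: read or simulate inputs, run every stage, write
    artifacts plus a manifest into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "inputs": {}}

    if config.simulate:
        universe = gene_universe(config.n_genes)
        signatures = generate_signatures(
            config.n_celltypes, config.genes_per_set, universe, seed=config.seed
        )
        cc = CohortConfig(
            n_studies=config.n_studies,
            samples_per_study=config.samples_per_study,
            n_genes=config.n_genes,
            n_deg=config.n_deg,
            seed=config.seed,
        )
        expr, samples = generate_cohort(cc, signatures)
        followup = generate_followup(
            samples.loc[samples["diagnosis"] == "hSTA"], seed=config.seed + 1
        )
        iom.write_expression(expr, outdir / "expression.tsv")
        iom.write_samples(samples, outdir / "samples.tsv")
        iom.write_gmt(signatures, outdir / "signatures.gmt")
        iom.write_followup(followup, outdir / "followup.tsv")
        manifest["stages"].append({"stage": "simulate", "config": dataclasses.asdict(cc)})
    else:
        for key in ("expression", "samples", "gmt"):
            if getattr(config, key) is None:
                raise ValueError(f"simulate=False requires the {key!r} path")
        expr = iom.read_expression(config.expression)
        samples = iom.read_samples(config.samples)
        signatures = iom.read_gmt(config.gmt)
        followup = iom.read_followup(config.followup) if config.followup else None
        for key in ("expression", "samples", "gmt", "followup"):
            p = getattr(config, key)
            if p:
                manifest["inputs"][key] = _sha256(Path(p))

    res = run_refit_pipeline(expr, samples, signatures, followup, cfg=config)

    iom.write_expression(res["expression"], outdir / "expression_adjusted.tsv")
    res["degs"].to_csv(outdir / "degs.tsv", sep="\t", float_format="%.17g")
    iom.write_expression(res["enrichment"], outdir / "enrichment.tsv")
    res["enrichment_test"].to_csv(outdir / "enrichment_test.tsv", sep="\t", float_format="%.17g")
    sel = res["selection"]
    iom.write_json(
        {
            "sizes": sel.sizes,
            "mean_auroc": {str(k): v for k, v in sel.mean_auroc.items()},
            "chosen_size": sel.chosen_size,
            "features": sel.features,
            "tol": sel.tol,
            "test_metrics": sel.metrics,
        },
        outdir / "selection.json",
    )
    model_payload = {
        "intercept": res["model"].intercept,
        "coefficients": res["model"].coefficients,
        "scaler": res["scaler"].to_dict(),
    }
    iom.write_json(model_payload, outdir / "score_model.json")
    scores_df = res["scores"].to_frame()
    scores_df["subphenotype"] = res["subphenotypes"].reindex(scores_df.index)
    scores_df.index.name = "sample_id"
    scores_df.to_csv(outdir / "scores.tsv", sep="\t", float_format="%.17g")
    iom.write_json({"mar_fraction": res["mar_fraction"]}, outdir / "reclassification.json")
    if "validation" in res:
        iom.write_json(res["validation"], outdir / "validation.json")

    manifest["stages"] += [
        {"stage": s, "params": p}
        for s, p in [
            ("preprocess", {"qn": config.qn, "combat": config.combat}),
            ("diffexp", {"alpha": config.alpha, "fc_thresh": config.fc_thresh, "n_perm": config.n_perm}),
            ("celltypes", {"n_sets": len(signatures)}),
            ("feature_selection", {"frac": config.frac, "folds": config.folds,
                                   "repeats": config.repeats, "tol": config.tol}),
            ("instascore", {"model": config.model, "scaler_scope": config.scaler_scope}),
        ]
    ]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    iom.write_json(manifest, outdir / "manifest.json")
    return outdir
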