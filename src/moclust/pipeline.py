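"""End-to-end discovery-pipeline orchestration.

``run_discovery_pipeline`` executes the whole workflow — cohort input
(generated or loaded), factor-grid model selection, survival-factor
screening, multi-omics clustering, Kaplan-Meier/log-rank comparison and
clinical characterization, optionally followed by label transfer to an
external cohort and pairwise gene-set enrichment — and writes every
artifact plus a machine-readable run manifest (seed, parameters,
versions).  A fixed seed makes the run bit-reproducible.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import contingency_summary, factor_clinical_association
from .clustering import define_mocs
from .enrichment import gsea, write_gene_sets
from .factor import select_model, top_loadings, variance_explained
from .io_preprocess import read_clinical, read_outcomes, read_view, assemble_dataset
from .survival import kaplan_meier, logrank_test, select_survival_factors
from .synthetic import (GeneratorConfig, generate_external_cohort,
                        generate_gene_sets, generate_multiomics_cohort)
from .transfer import (build_transfer_matrix, common_features, predict_clusters,
                       sam_multiclass, sam_union, train_ensemble)


@dataclass
class PipelineConfig:
    """Run configuration; either ``input_paths`` or a synthetic block."""

    seed: int = 0
    endpoint: str = "bc_death_metastasis_or_relapse"
    factor_grid: tuple = (10, 15, 20, 30)
    alpha: float = 0.05
    k_max: int = 10
    gap_B: int = 100
    ridge_lambda: float = 0.1
    include_all_samples: bool = True   # False: complete-profile sensitivity analysis
    synthetic: GeneratorConfig | None = None
    input_paths: dict | None = None    # {"views": {name: path}, "clinical":, "outcomes":}
    transfer: dict | None = None       # {"overlap":, "n_external":, "views": (...)}
    enrichment: dict | None = None     # {"n_sets":, "n_perm":, ...}
    sam_n_perm: int = 100
    sam_fdr: float = 0.01
    follow_up_truncation_months: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = GeneratorConfig(**raw["synthetic"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_dataset(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        gen = GeneratorConfig(**{**cfg.synthetic.__dict__,
                                 "seed": cfg.synthetic.seed or cfg.seed}) \
            if isinstance(cfg.synthetic, GeneratorConfig) else GeneratorConfig(**cfg.synthetic)
        return generate_multiomics_cohort(gen)
    paths = cfg.input_paths or {}
    for key in ("views", "clinical", "outcomes"):
        if key not in paths:
            raise ValueError(f"input_paths missing {key!r}")
    for p in [*paths["views"].values(), paths["clinical"], paths["outcomes"]]:
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    views = [read_view(p, name) for name, p in paths["views"].items()]
    return assemble_dataset(views, read_clinical(paths["clinical"]),
                            read_outcomes(paths["outcomes"])), None


def run_discovery_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the workflow; returns a result dict and writes artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        dataset, truth = _load_dataset(cfg)
        if not cfg.include_all_samples:
            # sensitivity analysis: restrict to samples profiled on every platform
            complete = np.ones(dataset.n_samples, dtype=bool)
            for v in dataset.views.values():
                complete &= v.observed
            dataset = dataset.subset(
                [s for s, ok in zip(dataset.sample_ids, complete) if ok])
        stage = "fit"
        report = select_model(dataset, grid=cfg.factor_grid,
                              ridge_lambda=cfg.ridge_lambda, seed=cfg.seed)
        model = report.models[report.chosen_K]
        ve = variance_explained(model, dataset)
        ve.r2.to_csv(outdir / "variance_explained.csv")
        model.factor_scores().to_csv(outdir / "factor_scores.csv")
        for view in dataset.views:
            top_loadings(model, 0, view).to_csv(
                outdir / f"top_loadings_F1_{view}.csv", index=False)

        stage = "screen"
        outcome = dataset.outcome(cfg.endpoint).reset_index()
        if cfg.follow_up_truncation_months is not None:
            from .survival import truncate_follow_up
            outcome = truncate_follow_up(outcome, cfg.follow_up_truncation_months)
        selected, crude, adjusted = select_survival_factors(
            model, outcome, dataset.clinical, alpha=cfg.alpha)
        forest = pd.DataFrame({
            "beta": crude.beta, "hr": crude.hr, "lo": crude.ci95["lo"],
            "hi": crude.ci95["hi"], "p": crude.wald_p,
        })
        forest.to_csv(outdir / "cox_factors_crude.csv")
        if adjusted is not None:
            pd.DataFrame({"beta": adjusted.beta, "hr": adjusted.hr,
                          "p": adjusted.wald_p}).to_csv(
                outdir / "cox_factors_age_adjusted.csv")
        if not selected:
            raise RuntimeError("no survival-associated factors at the chosen alpha")

        stage = "cluster"
        assignment = define_mocs(model, selected, k_max=cfg.k_max,
                                 seed=cfg.seed, B=cfg.gap_B)
        scores = model.factor_scores().iloc[:, selected]
        pd.concat([assignment.labels, scores], axis=1).to_csv(
            outdir / "cluster_assignment.csv")
        assignment.gap_curve.to_csv(outdir / "gap_curve.csv")

        stage = "survival"
        curves, risk = kaplan_meier(outcome, assignment.labels)
        risk.to_csv(outdir / "km_risk_table.csv")
        if assignment.k >= 2:
            lr = logrank_test(outcome, assignment.labels, pairwise=True)
            lr.pairwise.to_csv(outdir / "logrank_pairwise.csv")
        else:  # a single cluster admits no between-group comparison
            lr = None

        stage = "characterize"
        assoc = factor_clinical_association(model, dataset.clinical)
        assoc.to_csv(outdir / "factor_clinical_associations.csv", index=False)
        summary = contingency_summary(dataset.clinical, assignment.labels)
        summary.to_csv(outdir / "cluster_clinical_summary.csv", index=False)

        result = {
            "dataset": dataset, "truth": truth, "model": model,
            "selection_report": report, "selected_factors": selected,
            "crude_cox": crude, "adjusted_cox": adjusted,
            "assignment": assignment, "km_curves": curves,
            "logrank": lr, "summary": summary,
        }

        if cfg.transfer is not None and truth is not None:
            stage = "transfer"
            t = dict(cfg.transfer)
            external, ext_truth = generate_external_cohort(
                truth, overlap=t.get("overlap", 0.6),
                n_external=t.get("n_external", 300),
                seed=cfg.seed + 10_000, views=t.get("views"))
            shared = common_features(dataset, external)
            sam = sam_multiclass(
                dataset.views["mrna"].to_frame().dropna(),
                assignment.labels, n_perm=cfg.sam_n_perm,
                fdr_threshold=cfg.sam_fdr, seed=cfg.seed)
            degs = sam_union(sam)
            feats = {v: (sorted(set(f) & set(degs), key=f.index)
                         if v == "mrna" else f)
                     for v, f in shared.items()}
            X_train = build_transfer_matrix(dataset, feats)
            ens = train_ensemble(X_train, assignment.labels.reindex(X_train.index),
                                 seed=cfg.seed)
            X_ext = build_transfer_matrix(external, feats)
            pred = predict_clusters(ens, X_ext)
            pred.to_csv(outdir / "external_predictions.csv")
            result.update({"external": external, "external_truth": ext_truth,
                           "ensemble": ens, "predictions": pred, "degs": degs})

        if cfg.enrichment is not None and truth is not None:
            stage = "enrich"
            e = dict(cfg.enrichment)
            sets = generate_gene_sets(truth, n_sets=e.get("n_sets", 20),
                                      set_size_range=e.get("set_size_range", (15, 100)),
                                      enriched_fraction=e.get("enriched_fraction", 0.3),
                                      seed=cfg.seed)
            write_gene_sets(sets, outdir / "gene_sets_synthetic.gmt")
            labels = result["assignment"].labels
            mocs = sorted(labels.unique(), key=str)
            frames = []
            mrna = dataset.views["mrna"].to_frame().dropna()
            for a, b in [(x, y) for i, x in enumerate(mocs) for y in mocs[i + 1:]]:
                sub = labels[labels.isin([a, b])]
                res = gsea(mrna.loc[mrna.index.intersection(sub.index)],
                           sub, sets, n_perm=e.get("n_perm", 1000),
                           size_range=e.get("size_range", (15, 500)),
                           seed=cfg.seed)
                res["comparison"] = f"{a}_vs_{b}"
                frames.append(res)
            enr = pd.concat(frames)
            enr.to_csv(outdir / "enrichment_results.csv")
            result["enrichment"] = enr

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "endpoint": cfg.endpoint,
            "factor_grid": list(cfg.factor_grid),
            "alpha": cfg.alpha,
            "k_max": cfg.k_max,
            "chosen_K": report.chosen_K,
            "selected_factors": [f"F{i + 1}" for i in selected],
            "n_clusters": assignment.k,
            "versions": {"moclust": __version__,
                         "python": platform.python_version(),
                         "numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        result["manifest"] = manifest
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
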