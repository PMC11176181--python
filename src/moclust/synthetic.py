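"""Synthetic multi-view cohorts with known factors, clusters and survival.

The generator emulates the structure of a three-platform breast-tumor
cohort: a handful of latent factors shared across views, a small number
of prognostic factors carrying a Gaussian-mixture cluster structure,
sparse view-specific loadings, per-platform sample availability,
exponential proportional-hazards survival with uniform censoring, and
clinical covariates whose distributions shift with the latent cluster.
Every downstream stage (factor fitting, survival screening, clustering,
label transfer, enrichment) can therefore be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import MultiOmicsDataset, OmicsView

VIEW_NAMES = ("mrna", "protein", "metabolite")
_ID_PREFIX = {"mrna": "G", "protein": "P", "metabolite": "M"}

# per-cluster clinical sampling probabilities (worst-prognosis basal-like
# cluster first): grade gradient, hormone-receptor status, histology
_GRADE_P = np.array([
    [0.02, 0.08, 0.88, 0.00, 0.02],
    [0.10, 0.42, 0.45, 0.00, 0.03],
    [0.24, 0.49, 0.23, 0.00, 0.04],
])
_ER_POS = (0.08, 0.80, 0.85)
_PR_POS = (0.10, 0.65, 0.75)
_HER2_POS = (0.14, 0.20, 0.06)
_DUCTAL = (0.94, 0.86, 0.70)
_SUBTYPE_P = np.array([
    [0.74, 0.14, 0.02, 0.05, 0.05],
    [0.05, 0.20, 0.26, 0.42, 0.07],
    [0.08, 0.09, 0.34, 0.15, 0.34],
])
_SUBTYPES = ["Basal-like", "HER2-enriched", "LumA", "LumB", "Normal-like"]


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the discovery-cohort design: 335 patients, 20 latent
    factors of which 3 are prognostic and carry a 3-component cluster
    structure with mixing weights ~(0.15, 0.41, 0.44); per-view feature
    counts 2000/150/18 (transcript view down-scaled from array size for
    desk-scale runs); per-view observed counts 308/315/228; ~30% event
    rate under uniform censoring.
    """

    n_samples: int = 335
    k_total: int = 20
    k_prognostic: int = 3
    n_clusters: int = 3
    cluster_weights: tuple = (0.15, 0.41, 0.44)
    n_features: tuple = (2000, 150, 18)
    view_names: tuple = VIEW_NAMES
    separation: float = 5.0          # cluster split gap on each contrast axis, within-SD units
    extra_prognostic_sd: float = 1.5  # SD of prognostic axes carrying no mean structure
    loading_sparsity: float = 0.7    # fraction of zero loadings
    loading_scale: float = 0.5       # SD of nonzero loadings
    noise_sd: tuple = (1.0, 1.0, 1.0)
    missing_fractions: tuple = (27 / 335, 20 / 335, 107 / 335)
    baseline_hazard: float = 0.005   # events per month at zero linear predictor
    betas: tuple = (-0.8, 0.7, 0.6)  # log-hazard per prognostic-factor SD
    censoring_rate: float = 0.60
    endpoint: str = "bc_death_metastasis_or_relapse"
    de_effect_min: float = 0.5       # between/within SD ratio defining a true DE feature
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    Z_true: np.ndarray
    W_true: dict
    cluster_labels: np.ndarray          # 1-based
    cluster_centers: np.ndarray         # n_clusters x k_prognostic
    prognostic_sds: np.ndarray          # within-cluster SD per prognostic axis
    prognostic_factor_indices: list     # 0-based columns of Z_true
    survival_betas: np.ndarray
    de_features: dict                   # view -> list of feature ids
    noise_sd: dict
    missing_fractions: dict
    config: GeneratorConfig = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "cluster_labels": self.cluster_labels.tolist(),
            "prognostic_factor_indices": list(self.prognostic_factor_indices),
            "survival_betas": self.survival_betas.tolist(),
            "de_features": {k: list(v) for k, v in self.de_features.items()},
            "noise_sd": self.noise_sd,
            "missing_fractions": self.missing_fractions,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _cluster_centers(n_clusters: int, k_prognostic: int, separation: float,
                     weights: np.ndarray) -> np.ndarray:
    """Cluster centres built from weight-orthogonal group contrasts.

    c cluster means span at most c-1 dimensions, so the first
    min(c-1, Kp) prognostic axes carry Helmert-style contrasts (axis j
    splits cluster j from clusters j+1.., scaled so the split has gap
    ``separation`` and is weight-centred); axes beyond that carry no
    mean structure.  Weight-orthogonality keeps the population
    covariance diagonal in the true axes, so each prognostic factor is
    identifiable rather than mixed by rotation."""
    centers = np.zeros((n_clusters, k_prognostic))
    for j in range(min(n_clusters - 1, k_prognostic)):
        w_here = weights[j]
        w_rest = weights[j + 1:].sum()
        # a on cluster j, b on clusters > j, weight mean zero, a - b = sep
        a = separation * w_rest / (w_here + w_rest)
        b = a - separation
        centers[j, j] = a
        centers[j + 1:, j] = b
    return centers


def _prognostic_sds(cfg: GeneratorConfig) -> np.ndarray:
    """Within-cluster SD per prognostic axis: 1 on the contrast axes,
    inflated (and distinct) on axes without mean structure so every
    prognostic factor is separable from the unit-variance background."""
    sds = np.ones(cfg.k_prognostic)
    n_contrast = min(cfg.n_clusters - 1, cfg.k_prognostic)
    for i, j in enumerate(range(n_contrast, cfg.k_prognostic)):
        sds[j] = cfg.extra_prognostic_sd + 0.3 * i
    return sds


def _censoring_horizon(rates: np.ndarray, target_censoring: float) -> float:
    """Upper limit c of the U(0, c) censoring law hitting the target rate.

    For exponential event time with rate r and C ~ U(0, c),
    P(event observed) = 1 - (1 - exp(-r c)) / (r c).
    """
    def cens_frac(c):
        rc = rates * c
        return np.mean((1.0 - np.exp(-rc)) / rc) - target_censoring

    lo, hi = 1e-9, 1e9
    if cens_frac(hi) > 0:  # even a huge horizon censors more than requested
        return hi
    return brentq(cens_frac, lo, hi, xtol=1e-8)


def _feature_ids(view: str, d: int) -> list[str]:
    width = len(str(d))
    return [f"{_ID_PREFIX.get(view, view[:1].upper())}{i:0{width}d}" for i in range(1, d + 1)]


def generate_multiomics_cohort(config: GeneratorConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one discovery cohort plus its ground truth."""
    cfg = config
    if cfg.k_prognostic > cfg.k_total:
        raise ValueError("k_prognostic cannot exceed k_total")
    if len(cfg.n_features) != len(cfg.view_names) or len(cfg.noise_sd) != len(cfg.view_names):
        raise ValueError("per-view settings must match view_names length")
    rng = np.random.default_rng(cfg.seed)
    n, K, Kp = cfg.n_samples, cfg.k_total, cfg.k_prognostic

    weights = np.asarray(cfg.cluster_weights, dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(cfg.n_clusters, size=n, p=weights) + 1
    centers = _cluster_centers(cfg.n_clusters, Kp, cfg.separation, weights)
    prog_sds = _prognostic_sds(cfg)

    Z = rng.standard_normal((n, K))
    prog_idx = list(range(Kp))
    Z[:, prog_idx] = Z[:, prog_idx] * prog_sds + centers[labels - 1]

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    views: dict[str, OmicsView] = {}
    W_true: dict[str, np.ndarray] = {}
    de_features: dict[str, list[str]] = {}
    observed_masks = _draw_observed_masks(rng, n, cfg)

    for vi, (vname, d, sd) in enumerate(zip(cfg.view_names, cfg.n_features, cfg.noise_sd)):
        W = rng.standard_normal((d, K)) * cfg.loading_scale
        W[rng.random((d, K)) < cfg.loading_sparsity] = 0.0
        Y = Z @ W.T + rng.standard_normal((n, d)) * sd
        mask = observed_masks[:, vi]
        Y[~mask] = np.nan
        fids = _feature_ids(vname, d)
        views[vname] = OmicsView(vname, sample_ids, fids, Y, mask)
        W_true[vname] = W
        # truly differential features: between-cluster SD of the expected
        # value exceeds de_effect_min noise SDs
        mu = centers @ W[:, prog_idx].T            # n_clusters x d
        mbar = weights @ mu
        between_sd = np.sqrt(weights @ (mu - mbar) ** 2)
        de_features[vname] = [f for f, e in zip(fids, between_sd / sd)
                              if e > cfg.de_effect_min]

    betas = np.asarray(cfg.betas, dtype=float)
    if len(betas) < Kp:
        raise ValueError("need at least one beta per prognostic factor")
    betas = betas[:Kp]
    outcomes = _draw_survival(rng, Z[:, prog_idx], betas, cfg, sample_ids)
    clinical = _draw_clinical(rng, labels, sample_ids, cohort="synthetic-discovery")

    dataset = MultiOmicsDataset(views=views, clinical=clinical, outcomes=outcomes,
                                sample_ids=sample_ids)
    truth = GroundTruth(
        Z_true=Z, W_true=W_true, cluster_labels=labels, cluster_centers=centers,
        prognostic_sds=prog_sds, prognostic_factor_indices=prog_idx,
        survival_betas=betas,
        de_features=de_features,
        noise_sd=dict(zip(cfg.view_names, cfg.noise_sd)),
        missing_fractions=dict(zip(cfg.view_names, cfg.missing_fractions)),
        config=cfg,
    )
    return dataset, truth


def _draw_observed_masks(rng, n: int, cfg: GeneratorConfig) -> np.ndarray:
    """Per-view boolean masks with exactly round(n * (1 - missing)) observed,
    repaired so every sample is observed in at least one view."""
    m = len(cfg.view_names)
    masks = np.zeros((n, m), dtype=bool)
    for vi, frac in enumerate(cfg.missing_fractions):
        n_obs = int(round(n * (1.0 - frac)))
        obs = rng.choice(n, size=n_obs, replace=False)
        masks[obs, vi] = True
    orphan = np.flatnonzero(~masks.any(axis=1))
    for i in orphan:
        vi = rng.integers(m)
        donors = np.flatnonzero(masks[:, vi] & (masks.sum(axis=1) >= 2))
        masks[rng.choice(donors), vi] = False  # keep the view count exact
        masks[i, vi] = True
    return masks


def _draw_survival(rng, Z_prog, betas, cfg: GeneratorConfig, sample_ids) -> pd.DataFrame:
    if len(betas) != Z_prog.shape[1]:
        raise ValueError("one beta per prognostic factor required")
    lp = Z_prog @ betas
    rates = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    horizon = _censoring_horizon(rates, cfg.censoring_rate)
    c = rng.uniform(0.0, horizon, size=len(rates))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "time": time,
        "event": event,
        "endpoint": cfg.endpoint,
    })


def _cat(rng, n, levels, p):
    return np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=p)]


def _draw_clinical(rng, labels, sample_ids, cohort: str) -> pd.DataFrame:
    n = len(sample_ids)
    cl = labels - 1
    age = np.clip(rng.normal(56.2, 11.0, size=n), 25, 90).round(1)
    grade = np.empty(n, dtype=object)
    er = np.empty(n, dtype=object)
    pr = np.empty(n, dtype=object)
    her2 = np.empty(n, dtype=object)
    hist = np.empty(n, dtype=object)
    subtype = np.empty(n, dtype=object)
    for c in np.unique(cl):
        rows = np.flatnonzero(cl == c)
        k = len(rows)
        grade[rows] = _cat(rng, k, ["I", "II", "III", "IV", "NA"], _GRADE_P[c])
        er[rows] = _cat(rng, k, ["pos", "neg", "NA"],
                        [_ER_POS[c] * 0.98, (1 - _ER_POS[c]) * 0.98, 0.02])
        pr[rows] = _cat(rng, k, ["pos", "neg", "NA"],
                        [_PR_POS[c] * 0.98, (1 - _PR_POS[c]) * 0.98, 0.02])
        her2[rows] = _cat(rng, k, ["pos", "neg", "NA"],
                          [_HER2_POS[c] * 0.98, (1 - _HER2_POS[c]) * 0.98, 0.02])
        hist[rows] = _cat(rng, k, ["ductal", "non-ductal", "NA"],
                          [_DUCTAL[c] * 0.98, (1 - _DUCTAL[c]) * 0.98, 0.02])
        subtype[rows] = _cat(rng, k, _SUBTYPES, _SUBTYPE_P[c])
    tnbc = np.where(
        (er == "NA") | (pr == "NA") | (her2 == "NA"), "NA",
        np.where((er == "neg") & (pr == "neg") & (her2 == "neg"), "yes", "no"),
    )
    node = _cat(rng, n, ["pN0", "pN1mi", "pN1", "pN2", "pN3", "NA"],
                [0.60, 0.03, 0.25, 0.06, 0.03, 0.03])
    stage = _cat(rng, n, ["pTis", "pT1", "pT2", "pT3", "pT4", "NA"],
                 [0.03, 0.52, 0.37, 0.04, 0.00, 0.04])
    size_mm = np.where(
        stage == "pT1", rng.uniform(5, 20, n).round(1),
        np.where(np.isin(stage, ["pT2", "pT3"]), rng.uniform(21, 60, n).round(1), np.nan),
    )
    return pd.DataFrame({
        "sample_id": sample_ids, "age": age, "grade": grade,
        "node_status": node, "tumor_stage": stage, "tumor_size_mm": size_mm,
        "histology": hist, "er": er, "pr": pr, "her2": her2, "tnbc": tnbc,
        "subtype_label": subtype, "cohort": cohort,
    })


def generate_external_cohort(truth: GroundTruth, overlap, n_external: int, seed: int,
                             views: tuple | None = None) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw a validation cohort from the same generative law.

    Only ``ceil(overlap * D_m)`` features per retained view are emitted
    (seeded choice); shared feature ids are identical to discovery ids,
    so intersecting by id recovers them.  ``views`` restricts the cohort
    to a platform subset (e.g. a transcriptome-only cohort).
    """
    cfg = truth.config
    retained = tuple(views) if views is not None else tuple(cfg.view_names)
    if not retained:
        raise ValueError("at least one view must be retained")
    overlaps = ({v: float(overlap) for v in retained}
                if np.isscalar(overlap) else dict(overlap))
    for v, f in overlaps.items():
        if not (0.0 < f <= 1.0):
            raise ValueError(f"overlap for view {v!r} must be in (0, 1], got {f}")
    rng = np.random.default_rng(seed)
    n, K, Kp = n_external, cfg.k_total, cfg.k_prognostic

    weights = np.asarray(cfg.cluster_weights, dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(cfg.n_clusters, size=n, p=weights) + 1
    Z = rng.standard_normal((n, K))
    Z[:, truth.prognostic_factor_indices] = (
        Z[:, truth.prognostic_factor_indices] * truth.prognostic_sds
        + truth.cluster_centers[labels - 1])

    sample_ids = [f"E{i:04d}" for i in range(1, n + 1)]
    out_views: dict[str, OmicsView] = {}
    for vname in retained:
        W = truth.W_true[vname]
        d = W.shape[0]
        sd = truth.noise_sd[vname]
        n_keep = int(np.ceil(overlaps[vname] * d))
        if n_keep == 0:
            raise ValueError(f"view {vname!r}: zero retained features")
        keep = np.sort(rng.choice(d, size=n_keep, replace=False))
        Y = Z @ W[keep].T + rng.standard_normal((n, n_keep)) * sd
        fids = [ _feature_ids(vname, d)[i] for i in keep ]
        out_views[vname] = OmicsView(vname, sample_ids, fids, Y,
                                     np.ones(n, dtype=bool))
    outcomes = _draw_survival(rng, Z[:, truth.prognostic_factor_indices],
                              truth.survival_betas, cfg, sample_ids)
    clinical = _draw_clinical(rng, labels, sample_ids, cohort="synthetic-external")
    dataset = MultiOmicsDataset(views=out_views, clinical=clinical, outcomes=outcomes,
                                sample_ids=sample_ids)
    ext_truth = GroundTruth(
        Z_true=Z, W_true={v: truth.W_true[v] for v in retained},
        cluster_labels=labels, cluster_centers=truth.cluster_centers,
        prognostic_sds=truth.prognostic_sds,
        prognostic_factor_indices=truth.prognostic_factor_indices,
        survival_betas=truth.survival_betas,
        de_features=truth.de_features, noise_sd=truth.noise_sd,
        missing_fractions={v: 0.0 for v in retained}, config=cfg,
    )
    return dataset, ext_truth


def generate_gene_sets(truth: GroundTruth, n_sets: int = 20,
                       set_size_range: tuple = (15, 100),
                       enriched_fraction: float = 0.3, seed: int = 0,
                       view: str = "mrna") -> dict[str, list[str]]:
    """Fixture gene sets: enriched sets draw >=80% of members from the
    truly differential features, null sets from the non-differential pool."""
    rng = np.random.default_rng(seed)
    cfg = truth.config
    d = dict(zip(cfg.view_names, cfg.n_features))[view]
    all_ids = _feature_ids(view, d)
    de = list(truth.de_features[view])
    non_de = [f for f in all_ids if f not in set(de)]
    lo, hi = set_size_range
    if hi > len(all_ids):
        raise ValueError("requested set sizes exceed the feature pool")
    n_enriched = int(round(enriched_fraction * n_sets))
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            n_de = min(len(de), max(int(np.ceil(0.8 * size)), 1))
            members = list(rng.choice(de, size=n_de, replace=False))
            rest = [f for f in non_de if f not in members]
            members += list(rng.choice(rest, size=size - n_de, replace=False))
            name = f"ENRICHED_SET_{i + 1}"
        else:
            members = list(rng.choice(non_de, size=min(size, len(non_de)), replace=False))
            name = f"NULL_SET_{i + 1}"
        sets[name] = members
    return sets


def save_cohort(dataset: MultiOmicsDataset, outdir, truth: GroundTruth | None = None) -> None:
    """Write the cohort in the CSV schemas the readers consume."""
    from pathlib import Path
    from .io_preprocess import write_clinical, write_outcomes, write_view

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, view in dataset.views.items():
        write_view(view, outdir / f"view_{name}.csv")
    write_clinical(dataset.clinical, outdir / "clinical.csv")
    write_outcomes(dataset.outcomes, outdir / "outcomes.csv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
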