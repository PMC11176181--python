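"""Multi-view latent factor decomposition with missing-view handling.

The model is the standard group-factor decomposition

    Y_m = Z W_m^T + eps_m,   m = 1..M

with one factor-score matrix Z (samples × K) shared across views,
per-view weight matrices W_m (features × K) and per-view isotropic
residual noise.  It is estimated by ridge-penalized alternating least
squares on the per-view observed sample blocks:

* given Z, each W_m solves a ridge regression on that view's observed
  samples;
* given all W_m, each sample's score vector solves a ridge regression
  over only its observed views, weighted by the inverse noise variances;
* noise variances are re-estimated from residuals every sweep.

Each block update exactly maximizes the penalized Gaussian
log-likelihood, so the objective trace is non-decreasing and
convergence is monitored on its relative change.  Initialization is a
randomized SVD of the concatenated (noise-scaled, zero-imputed) blocks,
making the fit deterministic given the seed.  After fitting, factors
are canonicalized: ordered by total variance explained (descending)
and signed so the largest-magnitude loading is positive.

Views are preprocessed per fit: features centered (mandatory) and
unit-scaled (default) over observed samples, then the view rescaled to
total variance D_m so no single platform dominates by feature count
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .datasets import MultiOmicsDataset

_NOISE_FLOOR = 1e-10


@dataclass
class ViewScaler:
    """Frozen per-view centering/scaling parameters."""

    center: np.ndarray
    scale: np.ndarray       # per-feature divisor (ones when scaling off)
    view_scale: float       # global multiplier giving total variance D_m

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center) / self.scale * self.view_scale


@dataclass
class FactorModel:
    K: int
    Z: np.ndarray
    W: dict               # view -> D_m x K
    noise_var: dict       # view -> float
    objective_trace: np.ndarray
    ridge_lambda: float
    seed: int
    converged: bool
    scalers: dict = field(repr=False, default_factory=dict)
    sample_ids: list = field(repr=False, default_factory=list)
    feature_ids: dict = field(repr=False, default_factory=dict)

    def factor_scores(self) -> pd.DataFrame:
        cols = [f"F{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Z, index=self.sample_ids, columns=cols)


@dataclass
class VarianceExplained:
    r2: pd.DataFrame              # factors x views
    total_per_view: pd.Series
    total_per_factor: pd.Series   # pooled across views


@dataclass
class ModelSelectionReport:
    grid: list
    avg_vif: dict
    total_r2: dict
    score: dict
    chosen_K: int
    models: dict = field(repr=False, default_factory=dict)
    failures: dict = field(default_factory=dict)


def _prepare_views(dataset: MultiOmicsDataset, scale_features: bool):
    """Center/scale each view over its observed samples; returns
    (matrices with NaN off-mask, masks, scalers)."""
    mats, masks, scalers = {}, {}, {}
    for name, view in dataset.views.items():
        x = view.values
        obs = view.observed
        center = np.nanmean(x[obs], axis=0)
        if scale_features:
            sd = np.nanstd(x[obs], axis=0, ddof=0)
            sd[sd == 0] = 1.0
        else:
            sd = np.ones(x.shape[1])
        y = (x - center) / sd
        total_var = np.nansum(y[obs] ** 2) / max(obs.sum(), 1)
        vscale = np.sqrt(x.shape[1] / total_var) if total_var > 0 else 1.0
        y = y * vscale
        mats[name] = y
        masks[name] = obs
        scalers[name] = ViewScaler(center=center, scale=sd, view_scale=vscale)
    return mats, masks, scalers


def _objective(mats, masks, Z, W, noise_var, lam) -> float:
    ll = 0.0
    for name, y in mats.items():
        obs = masks[name]
        resid = y[obs] - Z[obs] @ W[name].T
        sse = float(np.sum(resid ** 2))
        n_el = resid.size
        s2 = noise_var[name]
        ll += -0.5 * (n_el * np.log(2 * np.pi * s2) + sse / s2)
    pen = 0.5 * lam * (float(np.sum(Z ** 2)) + sum(float(np.sum(w ** 2)) for w in W.values()))
    return ll - pen


def fit_factor_model(dataset: MultiOmicsDataset, K: int, ridge_lambda: float = 0.1,
                     tol: float = 1e-6, max_iter: int = 500, seed: int = 0,
                     scale_features: bool = True) -> FactorModel:
    """Fit the K-factor decomposition by penalized alternating least squares."""
    if K < 1:
        raise ValueError("K must be >= 1")
    n = dataset.n_samples
    d_total = sum(v.n_features for v in dataset.views.values())
    if K > n or K > d_total:
        raise ValueError(f"K={K} exceeds sample count {n} or total feature count {d_total}")
    mats, masks, scalers = _prepare_views(dataset, scale_features)
    names = list(mats)

    # initialization: randomized SVD of the concatenated, zero-imputed blocks
    concat = np.concatenate([np.nan_to_num(mats[m], nan=0.0) for m in names], axis=1)
    U, S, _ = randomized_svd(concat, n_components=K, random_state=seed)
    Z = U * S

    noise_var = {m: 1.0 for m in names}
    W = {m: np.zeros((mats[m].shape[1], K)) for m in names}
    lam = float(ridge_lambda)
    trace = []
    converged = False
    mask_matrix = np.column_stack([masks[m] for m in names])
    patterns = {}
    for i, row in enumerate(map(tuple, mask_matrix)):
        patterns.setdefault(row, []).append(i)
    patterns = {p: np.asarray(rows) for p, rows in patterns.items()}

    prev = -np.inf
    for _ in range(max_iter):
        # W update (ridge per view on observed samples)
        for m in names:
            obs = masks[m]
            Zs = Z[obs]
            A = Zs.T @ Zs + lam * noise_var[m] * np.eye(K)
            W[m] = np.linalg.solve(A, Zs.T @ mats[m][obs]).T
        # noise update
        for m in names:
            obs = masks[m]
            resid = mats[m][obs] - Z[obs] @ W[m].T
            noise_var[m] = max(float(np.mean(resid ** 2)), _NOISE_FLOOR)
        # Z update, grouped by view-observation pattern
        gram = {m: W[m].T @ W[m] / noise_var[m] for m in names}
        for pat, rows in patterns.items():
            A = lam * np.eye(K)
            B = np.zeros((len(rows), K))
            for mi, m in enumerate(names):
                if pat[mi]:
                    A = A + gram[m]
                    B += mats[m][rows] @ W[m] / noise_var[m]
            Z[rows] = np.linalg.solve(A, B.T).T
        obj = _objective(mats, masks, Z, W, noise_var, lam)
        trace.append(obj)
        if np.isfinite(prev) and abs(obj - prev) <= tol * abs(prev):
            converged = True
            break
        prev = obj

    if not converged:
        warnings.warn(f"factor model (K={K}) did not converge in {max_iter} sweeps",
                      stacklevel=2)

    model = FactorModel(
        K=K, Z=Z, W=W, noise_var=noise_var,
        objective_trace=np.asarray(trace), ridge_lambda=lam, seed=seed,
        converged=converged, scalers=scalers,
        sample_ids=list(dataset.sample_ids),
        feature_ids={m: list(dataset.views[m].feature_ids) for m in names},
    )
    _canonicalize(model, mats, masks)
    return model


def _canonicalize(model: FactorModel, mats, masks) -> None:
    """Order factors by pooled variance explained (desc); fix signs so the
    largest-|loading| weight entry is positive; tie order stable."""
    per_factor = _per_factor_pooled_r2(model, mats, masks)
    order = np.argsort(-per_factor, kind="stable")
    model.Z = model.Z[:, order]
    for m in model.W:
        model.W[m] = model.W[m][:, order]
    wcat = np.concatenate([model.W[m] for m in model.W], axis=0)
    for k in range(model.K):
        j = int(np.argmax(np.abs(wcat[:, k])))
        if wcat[j, k] < 0:
            model.Z[:, k] *= -1
            for m in model.W:
                model.W[m][:, k] *= -1


def _per_factor_pooled_r2(model: FactorModel, mats, masks) -> np.ndarray:
    ss_tot = 0.0
    ss_res = np.zeros(model.K)
    for m, y in mats.items():
        obs = masks[m]
        yo = y[obs]
        ss_tot += float(np.sum(yo ** 2))
        for k in range(model.K):
            recon = np.outer(model.Z[obs, k], model.W[m][:, k])
            ss_res[k] += float(np.sum((yo - recon) ** 2))
    return 1.0 - ss_res / ss_tot


def _model_matrices(model: FactorModel, dataset: MultiOmicsDataset):
    mats, masks = {}, {}
    for name, view in dataset.views.items():
        mats[name] = model.scalers[name].transform(view.values)
        masks[name] = view.observed
    return mats, masks


def variance_explained(model: FactorModel, dataset: MultiOmicsDataset) -> VarianceExplained:
    """Per-factor/per-view R² plus per-view and pooled totals.

    r2[k, m] = 1 - SS(Y_m - z_k w_mk^T) / SS(Y_m) over observed entries,
    floored at 0; per-view totals use the full reconstruction Z W_m^T.
    """
    mats, masks = _model_matrices(model, dataset)
    views = list(mats)
    r2 = np.zeros((model.K, len(views)))
    totals = {}
    for j, m in enumerate(views):
        obs = masks[m]
        yo = mats[m][obs]
        ss = float(np.sum(yo ** 2))
        for k in range(model.K):
            recon = np.outer(model.Z[obs, k], model.W[m][:, k])
            r2[k, j] = max(0.0, 1.0 - float(np.sum((yo - recon) ** 2)) / ss)
        full = model.Z[obs] @ model.W[m].T
        totals[m] = max(0.0, 1.0 - float(np.sum((yo - full) ** 2)) / ss)
    factors = [f"F{k + 1}" for k in range(model.K)]
    pooled = _per_factor_pooled_r2(model, mats, masks)
    return VarianceExplained(
        r2=pd.DataFrame(r2, index=factors, columns=views),
        total_per_view=pd.Series(totals),
        total_per_factor=pd.Series(np.maximum(pooled, 0.0), index=factors),
    )


def total_variance_explained(model: FactorModel, dataset: MultiOmicsDataset) -> float:
    """Pooled (all views jointly) R² of the full reconstruction."""
    mats, masks = _model_matrices(model, dataset)
    ss_tot = ss_res = 0.0
    for m, y in mats.items():
        obs = masks[m]
        yo = y[obs]
        ss_tot += float(np.sum(yo ** 2))
        ss_res += float(np.sum((yo - model.Z[obs] @ model.W[m].T) ** 2))
    return 1.0 - ss_res / ss_tot


def average_vif(model: FactorModel) -> float:
    """Mean variance inflation factor across factor columns.

    VIF_k = 1 / (1 - R²_k) with R²_k from OLS of Z[:, k] on the other
    columns (with intercept).  Perfect collinearity yields +inf with a
    warning.
    """
    Z = model.Z
    if model.K < 2:
        raise ValueError("average VIF needs at least two factors")
    vifs = []
    for k in range(model.K):
        y = Z[:, k]
        X = np.column_stack([np.ones(len(y)), np.delete(Z, k, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"factor {k + 1} perfectly collinear; VIF infinite", stacklevel=2)
            vifs.append(np.inf)
        else:
            vifs.append(1.0 / (1.0 - r2))
    return float(np.mean(vifs))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi - lo <= 0:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def selection_scores(r2_by_k: dict, vif_by_k: dict) -> dict:
    """score(K) = minmax(total R²) - minmax(average VIF) over the grid."""
    ks = sorted(r2_by_k)
    nr2 = _minmax(np.array([r2_by_k[k] for k in ks], dtype=float))
    nvif = _minmax(np.array([vif_by_k[k] for k in ks], dtype=float))
    return {k: float(a - b) for k, a, b in zip(ks, nr2, nvif)}


def select_model(dataset: MultiOmicsDataset, grid=(10, 15, 20, 30),
                 ridge_lambda: float = 0.1, tol: float = 1e-6,
                 max_iter: int = 500, seed: int = 0,
                 scale_features: bool = True) -> ModelSelectionReport:
    """Fit one model per factor count and pick the K balancing variance
    explained against factor multicollinearity.

    score(K) = minmax(total R²) - minmax(average VIF) over the grid;
    chosen_K = argmax, ties to the smaller K.
    """
    grid = sorted(set(int(k) for k in grid))
    models, vifs, r2s, failures = {}, {}, {}, {}
    for K in grid:
        try:
            m = fit_factor_model(dataset, K, ridge_lambda=ridge_lambda, tol=tol,
                                 max_iter=max_iter, seed=seed,
                                 scale_features=scale_features)
            models[K] = m
            vifs[K] = average_vif(m) if K >= 2 else 1.0
            r2s[K] = total_variance_explained(m, dataset)
        except Exception as exc:  # noqa: BLE001 - recorded, K removed from contention
            failures[K] = str(exc)
    if not models:
        raise RuntimeError(f"all factor-grid fits failed: {failures}")
    ks = sorted(models)
    score = selection_scores(r2s, vifs)
    best = max(score.values())
    # parsimony tie-break: scores within 1% of the normalized range count
    # as ties and resolve to the smaller K
    chosen = min(k for k in ks if score[k] >= best - 0.01)
    return ModelSelectionReport(grid=grid, avg_vif=vifs, total_r2=r2s,
                                score=score, chosen_K=chosen,
                                models=models, failures=failures)


def top_loadings(model: FactorModel, factor_index: int, view: str,
                 n: int = 25, threshold: float = 0.9) -> pd.DataFrame:
    """Top-|loading| features of one factor in one view.

    Loadings are rescaled to a maximum of 1 within the view-factor;
    entries above the display threshold are flagged.  Ties break by
    feature id; n beyond the view size returns all features.
    """
    if view not in model.W:
        raise KeyError(f"unknown view {view!r}")
    if not (0 <= factor_index < model.K):
        raise IndexError(f"factor index {factor_index} outside 0..{model.K - 1}")
    w = np.abs(model.W[view][:, factor_index])
    scale = w.max()
    scaled = w / scale if scale > 0 else w
    df = pd.DataFrame({
        "feature": model.feature_ids[view],
        "abs_loading": w,
        "scaled_loading": scaled,
    })
    df["important"] = df["scaled_loading"] > threshold
    df = df.sort_values(["scaled_loading", "feature"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df.head(min(n, len(df)))
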