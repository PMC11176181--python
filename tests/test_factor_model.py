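import numpy as np
import pandas as pd
import pytest

from moclust import (GeneratorConfig, average_vif, fit_factor_model,
                     generate_multiomics_cohort, select_model, top_loadings,
                     total_variance_explained, variance_explained)
from moclust.datasets import MultiOmicsDataset, OmicsView
from moclust.factor import FactorModel, selection_scores


def _single_view_dataset(values, name="v"):
    n = values.shape[0]
    ids = [f"s{i}" for i in range(n)]
    view = OmicsView(name, ids, [f"f{j}" for j in range(values.shape[1])],
                     values, np.ones(n, bool))
    clinical = pd.DataFrame({"sample_id": ids, "age": 50.0})
    outcomes = pd.DataFrame({"sample_id": ids, "time": 1.0, "event": 0,
                             "endpoint": "all_cause"})
    return MultiOmicsDataset(views={name: view}, clinical=clinical,
                             outcomes=outcomes, sample_ids=ids)


def _factor_model_from_scores(Z):
    return FactorModel(K=Z.shape[1], Z=Z, W={}, noise_var={},
                       objective_trace=np.array([0.0]), ridge_lambda=0.1,
                       seed=0, converged=True)


class TestFit:
    def test_exact_low_rank_single_view(self, rng):
        Z = rng.standard_normal((60, 2))
        W = rng.standard_normal((30, 2))
        ds = _single_view_dataset(Z @ W.T)
        m = fit_factor_model(ds, K=2, ridge_lambda=1e-6, tol=1e-12,
                             max_iter=2000, seed=0, scale_features=False)
        assert total_variance_explained(m, ds) >= 0.999

    def test_objective_trace_non_decreasing(self, small_model):
        tr = small_model.objective_trace
        assert np.all(np.diff(tr) >= -1e-7 * np.abs(tr[:-1]))

    def test_seed_reproducible_bit_exact(self, small_cohort):
        dataset, _ = small_cohort
        a = fit_factor_model(dataset, K=4, seed=3, max_iter=40)
        b = fit_factor_model(dataset, K=4, seed=3, max_iter=40)
        assert np.array_equal(a.Z, b.Z)
        assert all(np.array_equal(a.W[v], b.W[v]) for v in a.W)

    def test_sample_with_single_observed_view_is_scored(self, small_cohort):
        dataset, _ = small_cohort
        # force one sample to be metabolite-only
        views = {n: OmicsView(v.name, v.sample_ids, v.feature_ids,
                              v.values.copy(), v.observed.copy())
                 for n, v in dataset.views.items()}
        sid = 0
        for name in ("mrna", "protein"):
            views[name].observed[sid] = False
            views[name].values[sid] = np.nan
        views["metabolite"].observed[sid] = True
        views["metabolite"].values[sid] = np.nan_to_num(
            views["metabolite"].values[sid], nan=0.0)
        ds = MultiOmicsDataset(views=views, clinical=dataset.clinical,
                               outcomes=dataset.outcomes,
                               sample_ids=dataset.sample_ids)
        m = fit_factor_model(ds, K=3, max_iter=30, seed=0)
        assert np.all(np.isfinite(m.Z[sid]))

    def test_invalid_k_rejected(self, small_cohort):
        dataset, _ = small_cohort
        with pytest.raises(ValueError):
            fit_factor_model(dataset, K=0)
        with pytest.raises(ValueError):
            fit_factor_model(dataset, K=dataset.n_samples + 1)

    def test_pca_equivalence_single_view(self, rng):
        """With one complete view and a vanishing ridge, the K-factor
        variance explained equals the leading-K PCA variance fraction."""
        x = rng.standard_normal((40, 15)) @ rng.standard_normal((15, 15))
        x = x - x.mean(axis=0)
        ds = _single_view_dataset(x)
        K = 4
        m = fit_factor_model(ds, K=K, ridge_lambda=1e-9, tol=1e-15,
                             max_iter=5000, seed=0, scale_features=False)
        sv = np.linalg.svd(x, compute_uv=False)
        pca_frac = (sv[:K] ** 2).sum() / (sv ** 2).sum()
        assert abs(total_variance_explained(m, ds) - pca_frac) < 1e-6


class TestVarianceExplained:
    def test_rank_one_noise_free_is_full(self, rng):
        z = rng.standard_normal(50)
        w = rng.standard_normal(12)
        ds = _single_view_dataset(np.outer(z, w))
        m = fit_factor_model(ds, K=1, ridge_lambda=1e-8, tol=1e-12,
                             max_iter=1000, seed=0, scale_features=False)
        ve = variance_explained(m, ds)
        assert ve.r2.iloc[0, 0] > 0.999

    def test_view_driven_by_one_factor_identified(self, rng):
        # factor 1 drives only view "a"; its r2 must peak there
        z = rng.standard_normal((80, 2))
        ya = np.outer(z[:, 0], rng.standard_normal(20)) + 0.01 * rng.standard_normal((80, 20))
        yb = np.outer(z[:, 1], rng.standard_normal(20)) + 0.01 * rng.standard_normal((80, 20))
        ids = [f"s{i}" for i in range(80)]
        views = {
            "a": OmicsView("a", ids, [f"a{j}" for j in range(20)], ya, np.ones(80, bool)),
            "b": OmicsView("b", ids, [f"b{j}" for j in range(20)], yb, np.ones(80, bool)),
        }
        clinical = pd.DataFrame({"sample_id": ids, "age": 50.0})
        outcomes = pd.DataFrame({"sample_id": ids, "time": 1.0, "event": 0,
                                 "endpoint": "all_cause"})
        ds = MultiOmicsDataset(views=views, clinical=clinical, outcomes=outcomes,
                               sample_ids=ids)
        m = fit_factor_model(ds, K=2, seed=0, scale_features=False)
        ve = variance_explained(m, ds)
        # each factor explains essentially one view
        top_views = ve.r2.idxmax(axis=1)
        assert set(top_views) == {"a", "b"}

    def test_permuting_factors_permutes_rows(self, small_model, small_cohort):
        dataset, _ = small_cohort
        ve = variance_explained(small_model, dataset)
        permuted = FactorModel(
            K=small_model.K, Z=small_model.Z[:, ::-1],
            W={v: w[:, ::-1] for v, w in small_model.W.items()},
            noise_var=small_model.noise_var,
            objective_trace=small_model.objective_trace,
            ridge_lambda=small_model.ridge_lambda, seed=0, converged=True,
            scalers=small_model.scalers, sample_ids=small_model.sample_ids,
            feature_ids=small_model.feature_ids)
        ve2 = variance_explained(permuted, dataset)
        assert np.allclose(ve.r2.to_numpy(), ve2.r2.to_numpy()[::-1], atol=1e-12)


class TestVIF:
    def test_orthogonal_factors_give_one(self):
        Z = np.diag([1.0, 2.0, 3.0]) @ np.eye(3, 5)
        Z = np.vstack([np.eye(3), -np.eye(3)])  # orthogonal, mean-zero columns
        assert average_vif(_factor_model_from_scores(Z)) == pytest.approx(1.0)

    def test_closed_form_at_correlation_08(self, rng):
        z1 = rng.standard_normal(300)
        z1 = (z1 - z1.mean()) / z1.std()
        e = rng.standard_normal(300)
        e -= e.mean()
        e -= z1 * (z1 @ e) / (z1 @ z1)
        e /= e.std()
        z2 = 0.8 * z1 + np.sqrt(1 - 0.64) * e
        vif = average_vif(_factor_model_from_scores(np.column_stack([z1, z2])))
        assert vif == pytest.approx(1.0 / (1.0 - 0.64), abs=1e-9)

    def test_invariant_to_column_rescaling(self, rng):
        Z = rng.standard_normal((100, 4))
        base = average_vif(_factor_model_from_scores(Z))
        Z2 = Z.copy()
        Z2[:, 2] *= 37.0
        assert average_vif(_factor_model_from_scores(Z2)) == pytest.approx(base)

    def test_collinear_factors_flagged_infinite(self, rng):
        z = rng.standard_normal(50)
        Z = np.column_stack([z, 2 * z])
        with pytest.warns(UserWarning, match="collinear"):
            assert np.isinf(average_vif(_factor_model_from_scores(Z)))


class TestModelSelection:
    def test_rank_three_data_selects_three(self, rng):
        Z = rng.standard_normal((80, 3)) * np.array([3.0, 2.0, 1.5])
        W = rng.standard_normal((60, 3))
        ds = _single_view_dataset(Z @ W.T + 0.05 * rng.standard_normal((80, 60)))
        report = select_model(ds, grid=(2, 3, 4), seed=0, max_iter=200)
        assert report.chosen_K == 3

    def test_single_element_grid(self, small_cohort):
        dataset, _ = small_cohort
        report = select_model(dataset, grid=(3,), seed=0, max_iter=30)
        assert report.chosen_K == 3

    def test_score_arithmetic_matches_hand_normalization(self):
        r2 = {10: 0.40, 15: 0.50, 20: 0.58, 30: 0.60}
        vif = {10: 1.1, 15: 1.3, 20: 1.5, 30: 2.9}
        scores = selection_scores(r2, vif)
        # hand-computed min-max arithmetic on the four rows
        assert scores[10] == pytest.approx((0.40 - 0.40) / 0.20 - 0.0)
        assert scores[15] == pytest.approx(0.10 / 0.20 - 0.20 / 1.80)
        assert scores[20] == pytest.approx(0.18 / 0.20 - 0.40 / 1.80)
        assert scores[30] == pytest.approx(1.0 - 1.0)
        assert max(scores, key=scores.get) == 20


class TestTopLoadings:
    def test_dominant_feature_first_with_unit_scale(self, small_model):
        view = "protein"
        m = small_model
        w = m.W[view].copy()
        w[5, 0] = 10 * np.abs(w[:, 0]).max()
        m2 = FactorModel(K=m.K, Z=m.Z, W={**m.W, view: w}, noise_var=m.noise_var,
                         objective_trace=m.objective_trace, ridge_lambda=0.1,
                         seed=0, converged=True, scalers=m.scalers,
                         sample_ids=m.sample_ids, feature_ids=m.feature_ids)
        top = top_loadings(m2, 0, view, n=5)
        assert top.iloc[0]["feature"] == m.feature_ids[view][5]
        assert top.iloc[0]["scaled_loading"] == 1.0
        assert top.iloc[0]["important"]

    def test_requested_row_count(self, small_model):
        assert len(top_loadings(small_model, 0, "mrna", n=25)) == 25

    def test_threshold_flag_rule(self, small_model):
        top = top_loadings(small_model, 1, "mrna", n=400)
        assert (top["important"] == (top["scaled_loading"] > 0.9)).all()

    def test_n_beyond_view_size_returns_all(self, small_model):
        assert len(top_loadings(small_model, 0, "metabolite", n=999)) == 12


def test_prognostic_subspace_recovered(default_cohort):
    """Fitted factors recover the planted prognostic structure at study
    conditions: the cluster-defining contrast axes are recovered as a
    subspace (principal angles < 10 degrees), and the variance-only
    prognostic axis is recovered as an individual factor (matched
    absolute correlation > 0.9; being a pure variance component among
    many unit-variance background factors, its direction carries more
    sampling leakage than the mean-contrast axes, so the subspace-angle
    oracle applies to the contrast axes)."""
    dataset, truth = default_cohort
    model = fit_factor_model(dataset, K=truth.config.k_total, seed=1)
    Zt = truth.Z_true[:, truth.prognostic_factor_indices]
    C = np.abs(np.corrcoef(np.hstack([Zt, model.Z]).T)[:Zt.shape[1], Zt.shape[1]:])
    cols = [int(C[j].argmax()) for j in range(Zt.shape[1])]
    assert len(set(cols)) == Zt.shape[1]
    n_contrast = truth.config.n_clusters - 1
    Qa, _ = np.linalg.qr(Zt[:, :n_contrast] - Zt[:, :n_contrast].mean(axis=0))
    fitted = model.Z[:, cols[:n_contrast]]
    Qb, _ = np.linalg.qr(fitted - fitted.mean(axis=0))
    sv = np.clip(np.linalg.svd(Qa.T @ Qb, compute_uv=False), -1, 1)
    angles = np.degrees(np.arccos(sv))
    assert np.all(angles < 10.0)
    for j in range(n_contrast, Zt.shape[1]):
        assert C[j, cols[j]] > 0.9
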