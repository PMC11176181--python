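import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from moclust import (common_features, generate_external_cohort,
                     predict_clusters, sam_two_class, train_ensemble)
from moclust.transfer import EnsembleModel, build_transfer_matrix, sam_union


def _frame(rng, n, d, prefix="g"):
    return pd.DataFrame(rng.standard_normal((n, d)),
                        index=[f"s{i}" for i in range(n)],
                        columns=[f"{prefix}{j}" for j in range(d)])


class TestSAM:
    def test_s0_zero_equals_t_denominator_oracle(self, rng):
        X = _frame(rng, 20, 40)
        labels = pd.Series(["a"] * 8 + ["b"] * 12, index=X.index)
        res = sam_two_class(X, labels, n_perm=10, seed=0, s0=0.0)
        a = X[labels == "a"].to_numpy()
        b = X[labels == "b"].to_numpy()
        num = b.mean(0) - a.mean(0)
        ss = ((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)
        se = np.sqrt((1 / 8 + 1 / 12) * ss / 18)
        assert np.allclose(res.table["d_stat"].to_numpy(), num / se, atol=1e-12)

    def test_constant_feature_never_selected(self, rng):
        X = _frame(rng, 16, 10)
        X["g0"] = 3.14
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=X.index)
        res = sam_two_class(X, labels, n_perm=50, seed=0)
        row = res.table.set_index("feature").loc["g0"]
        assert row["d_stat"] == 0.0
        assert not row["selected"]

    def test_null_selection_rate_controlled(self):
        fracs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = _frame(rng, 30, 300)
            labels = pd.Series(["a"] * 15 + ["b"] * 15, index=X.index)
            res = sam_two_class(X, labels, n_perm=100, seed=seed)
            fracs.append(len(res.selected) / 300)
        assert np.mean(fracs) <= 0.01

    def test_qvalues_monotone_in_abs_d(self, rng):
        X = _frame(rng, 24, 60)
        X.iloc[:12, :5] += 2.0
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=X.index)
        res = sam_two_class(X, labels, n_perm=60, seed=1)
        tab = res.table.sort_values("d_stat", key=lambda s: -s.abs())
        assert (np.diff(tab["q_value"].to_numpy()) >= -1e-12).all()

    def test_exhaustive_enumeration_small_samples(self, rng):
        X = _frame(rng, 6, 8)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=X.index)
        res = sam_two_class(X, labels, n_perm=1000, seed=0)
        assert res.n_permutations == 20  # C(6,3)

    def test_true_shift_detected(self, rng):
        X = _frame(rng, 40, 100)
        X.iloc[20:, :10] += 3.0
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=X.index)
        res = sam_two_class(X, labels, n_perm=100, seed=0)
        shifted = {f"g{j}" for j in range(10)}
        assert shifted <= set(res.selected)


class TestCommonFeatures:
    def test_identical_cohorts_full_intersection(self, small_cohort):
        dataset, _ = small_cohort
        shared = common_features(dataset, dataset)
        for name, view in dataset.views.items():
            assert shared[name] == list(view.feature_ids)

    def test_overlap_half_count(self, small_cohort):
        dataset, truth = small_cohort
        ext, _ = generate_external_cohort(truth, overlap=0.5, n_external=30, seed=0)
        shared = common_features(dataset, ext)
        for name in shared:
            d = dataset.views[name].n_features
            assert len(shared[name]) == int(np.ceil(0.5 * d))

    def test_absent_view_dropped(self, small_cohort):
        dataset, truth = small_cohort
        ext, _ = generate_external_cohort(truth, overlap=0.8, n_external=30,
                                          seed=0, views=("mrna",))
        shared = common_features(dataset, ext)
        assert set(shared) == {"mrna"}


class TestEnsemble:
    @staticmethod
    def _separable(rng, n_per=30, d=9):
        # class centres on a simplex (block k shifted for class k), so the
        # classes are linearly separable and non-collinear
        centers = np.zeros((3, d))
        for k in range(3):
            centers[k, k * (d // 3):(k + 1) * (d // 3)] = 5.0
        X = pd.DataFrame(
            np.vstack([rng.normal(c, 0.3, size=(n_per, d)) for c in centers]),
            index=[f"s{i}" for i in range(3 * n_per)],
            columns=[f"g{j}" for j in range(d)])
        y = pd.Series(np.repeat(["MOC1", "MOC2", "MOC3"], n_per), index=X.index)
        return X, y

    def test_separable_data_self_prediction_perfect(self, rng):
        X, y = self._separable(rng)
        ens = train_ensemble(X, y, seed=0, n_trees=100)
        Xs = ens.scaler.transform(X.to_numpy())
        for est in ens.classifiers.values():
            assert (est.predict(Xs) == y.to_numpy()).all()

    def test_same_seed_same_hyperparameters(self, rng):
        X, y = self._separable(rng, n_per=20)
        a = train_ensemble(X, y, seed=4, n_trees=50)
        b = train_ensemble(X, y, seed=4, n_trees=50)
        assert a.chosen_params == b.chosen_params

    def test_label_permutation_gives_chance_auc(self):
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = _frame(rng, 60, 15)
            y = pd.Series(rng.permutation(np.repeat(["MOC1", "MOC2", "MOC3"], 20)),
                          index=X.index)
            ens = train_ensemble(X, y, seed=seed, n_trees=50)
            aucs.extend(ens.cv_auc.values())
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_small_class_rejected(self, rng):
        X = _frame(rng, 12, 5)
        y = pd.Series(["MOC1"] * 3 + ["MOC2"] * 9, index=X.index)
        with pytest.raises(ValueError, match="<5 samples"):
            train_ensemble(X, y, seed=0)


class TestPredict:
    @staticmethod
    def _stub_ensemble(probas, classes=("MOC1", "MOC2", "MOC3")):
        class Stub:
            def __init__(self, p):
                self.p = np.asarray(p)
                self.classes_ = np.asarray(classes)

            def predict_proba(self, X):
                return np.tile(self.p, (len(X), 1))

        scaler = StandardScaler(with_mean=False, with_std=False).fit([[0.0]])
        return EnsembleModel(
            classifiers={f"c{i}": Stub(p) for i, p in enumerate(probas)},
            cv_auc={}, chosen_params={}, classes=list(classes),
            feature_list=["f1"], scaler=scaler)

    def test_average_and_documented_tie_rule(self):
        ens = self._stub_ensemble([(0.6, 0.3, 0.1), (0.2, 0.5, 0.3),
                                   (0.4, 0.4, 0.2)])
        pred = predict_clusters(ens, pd.DataFrame({"f1": [0.0]}))
        assert np.allclose(pred[["p_MOC1", "p_MOC2", "p_MOC3"]].iloc[0],
                           [0.4, 0.4, 0.2])
        assert pred["assigned"].iloc[0] == "MOC1"
        assert bool(pred["tie"].iloc[0])

    def test_probabilities_on_simplex(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 6)),
                         columns=[f"g{j}" for j in range(6)])
        y = pd.Series(np.repeat(["MOC1", "MOC2"], [12, 13]), index=X.index)
        ens = train_ensemble(X, y, seed=0, n_trees=50)
        pred = predict_clusters(ens, X)
        probs = pred[[c for c in pred.columns if c.startswith("p_")]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= -1e-12).all()

    def test_missing_features_rejected(self):
        ens = self._stub_ensemble([(1.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="missing"):
            predict_clusters(ens, pd.DataFrame({"other": [1.0]}))


def test_transfer_matrix_complete_cases(small_cohort):
    dataset, _ = small_cohort
    feats = {name: list(v.feature_ids[:5]) for name, v in dataset.views.items()}
    X = build_transfer_matrix(dataset, feats)
    assert not X.isna().any().any()
    obs_all = np.ones(dataset.n_samples, bool)
    for v in dataset.views.values():
        obs_all &= v.observed
    assert len(X) == obs_all.sum()


def test_sam_union_preserves_first_appearance_order():
    class R:
        def __init__(self, sel):
            self.selected = sel

    out = sam_union({(1, 2): R(["b", "a"]), (1, 3): R(["a", "c"])})
    assert out == ["b", "a", "c"]
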