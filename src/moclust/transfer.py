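"""Cluster-label transfer to external cohorts.

Pipeline: (1) SAM (significance analysis of microarrays) picks
differentially expressed transcripts between cluster pairs on the
discovery cohort (union over pairs); (2) features are intersected with
the external cohort's assays; (3) a random-forest / linear-SVM / PLS-DA
ensemble is tuned by 5-fold stratified CV on macro one-vs-rest AUC,
refit on all discovery samples, and (4) external samples receive the
class with the highest classifier-averaged probability.

SAM and the PLS-DA probability wrapper are implemented here (no
canonical library contract); the forest and SVM are scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import MultiOmicsDataset


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SAMResult:
    table: pd.DataFrame       # feature, d_stat, s, q_value, selected
    s0: float
    n_permutations: int
    fdr_threshold: float

    @property
    def selected(self) -> list:
        return list(self.table.loc[self.table["selected"], "feature"])


def _sam_d(X1: np.ndarray, X2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated two-sample statistic d = (mean2 - mean1)/(s + s0) with s
    the pooled standard error per feature (features in columns)."""
    n1, n2 = len(X1), len(X2)
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    ss = ((X1 - m1) ** 2).sum(axis=0) + ((X2 - m2) ** 2).sum(axis=0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2.0))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (m2 - m1) / np.where(denom > 0, denom, 1.0), 0.0)
    return d, s


def _tusher_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the s-percentile candidate (0,5,...,100) minimizing the
    coefficient of variation of the d spread across s-quantile windows."""
    candidates = np.percentile(s, np.arange(0, 101, 5))
    qs = np.quantile(s, np.linspace(0, 1, 11))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = r / (s + s0)
        mads = []
        for lo, hi in zip(qs[:-1], qs[1:]):
            w = d[(s >= lo) & (s <= hi)]
            if len(w) >= 3:
                mads.append(np.median(np.abs(w - np.median(w))) / 0.6745)
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_two_class(X: pd.DataFrame, labels: pd.Series, n_perm: int = 100,
                  fdr_threshold: float = 0.01, seed: int = 0,
                  s0: float | None = None) -> SAMResult:
    """Two-class SAM with permutation-based false-discovery q-values.

    ``X`` is samples × features.  Null d-distributions come from label
    permutations (exhaustive when fewer distinct permutations than
    ``n_perm`` exist); the q-value at each |d| cutoff is the median
    permutation false-call count over the observed call count,
    monotonized to be non-increasing in |d|.
    """
    labels = pd.Series(labels).reindex(X.index) if hasattr(labels, "reindex") else pd.Series(labels)
    classes = sorted(labels.dropna().unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    g1 = X[labels == classes[0]].to_numpy(dtype=float)
    g2 = X[labels == classes[1]].to_numpy(dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two samples per class")
    n1 = len(g1)
    pooled = np.vstack([g1, g2])
    n = len(pooled)
    _, s = _sam_d(g1, g2, 0.0)
    r = g2.mean(axis=0) - g1.mean(axis=0)
    if s0 is None:
        s0 = _tusher_s0(r, s)
    denom = s + s0
    d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)

    from math import comb
    n_distinct = comb(n, n1)
    rng = np.random.default_rng(seed)
    if n_perm >= n_distinct:
        idx_sets = list(combinations(range(n), n1))
    else:
        idx_sets = [rng.permutation(n)[:n1] for _ in range(n_perm)]
    null_d = np.empty((len(idx_sets), X.shape[1]))
    all_idx = np.arange(n)
    for b, idx in enumerate(idx_sets):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        null_d[b], _ = _sam_d(pooled[sel], pooled[~sel], s0)

    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    cuts = abs_d[order]
    # false calls at each cutoff |d_(i)|: median over permutations
    sorted_null = np.sort(np.abs(null_d), axis=1)
    n_feat = X.shape[1]
    counts = n_feat - np.vstack(
        [np.searchsorted(row, cuts, side="left") for row in sorted_null])
    false_calls = np.median(counts, axis=0)
    called = np.arange(1, len(cuts) + 1)
    q_sorted = np.clip(false_calls / called, 0.0, 1.0)
    # monotonize: q non-increasing as |d| grows <=> non-decreasing along the
    # descending-|d| order
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    table = pd.DataFrame({
        "feature": X.columns,
        "d_stat": d,
        "s": s,
        "q_value": q,
        "selected": q < fdr_threshold,
    })
    return SAMResult(table=table, s0=float(s0), n_permutations=len(idx_sets),
                     fdr_threshold=fdr_threshold)


def sam_multiclass(X: pd.DataFrame, labels: pd.Series, n_perm: int = 100,
                   fdr_threshold: float = 0.01, seed: int = 0) -> dict:
    """Pairwise SAM between all cluster pairs; the union of selected
    features is the DEG panel used for classifier training."""
    classes = sorted(pd.Series(labels).dropna().unique(), key=str)
    results = {}
    for i, (a, b) in enumerate(combinations(classes, 2)):
        mask = labels.isin([a, b])
        results[(a, b)] = sam_two_class(X[mask], labels[mask], n_perm=n_perm,
                                        fdr_threshold=fdr_threshold, seed=seed + i)
    return results


def sam_union(results: dict) -> list:
    out: list = []
    seen: set = set()
    for res in results.values():
        for f in res.selected:
            if f not in seen:
                seen.add(f)
                out.append(f)
    return out


# ---------------------------------------------------------------------------
# feature intersection


def common_features(discovery: MultiOmicsDataset,
                    external: MultiOmicsDataset) -> dict:
    """Per-view shared feature ids (discovery order); views absent from
    the external cohort are dropped."""
    shared: dict[str, list] = {}
    for name, view in discovery.views.items():
        if name not in external.views:
            continue
        ext = set(external.views[name].feature_ids)
        shared[name] = [f for f in view.feature_ids if f in ext]
    total = sum(len(v) for v in shared.values())
    if total == 0:
        raise ValueError("no shared features between the cohorts")
    return shared


# ---------------------------------------------------------------------------
# PLS-DA


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares discriminant analysis with probabilities.

    The class response is one-hot encoded and regressed by PLS; the
    predicted scores are mapped through a softmax to the simplex.  This
    probability mapping is a package choice, isolated here so an
    alternative (e.g. Gaussian Bayes on the latent scores) can be
    substituted.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        Y = np.zeros((len(y), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            Y[np.asarray(y) == c, j] = 1.0
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(np.asarray(X, dtype=float), Y)
        return self

    def predict_proba(self, X):
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    classifiers: dict                 # name -> fitted estimator
    cv_auc: dict                      # name -> best CV macro-OVR AUC
    chosen_params: dict
    classes: list
    feature_list: list
    scaler: StandardScaler = field(repr=False, default=None)


def _cv_auc(estimator, X, y, seed: int) -> float:
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    aucs = []
    classes = np.unique(y)
    for tr, te in skf.split(X, y):
        est = estimator.__class__(**estimator.get_params())
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        # align columns to the global class list
        aligned = np.zeros((len(te), len(classes)))
        for j, c in enumerate(est.classes_):
            aligned[:, list(classes).index(c)] = proba[:, j]
        if len(classes) == 2:
            aucs.append(roc_auc_score(y[te] == classes[1], aligned[:, 1]))
        else:
            aucs.append(roc_auc_score(y[te], aligned, multi_class="ovr",
                                      average="macro", labels=classes))
    return float(np.mean(aucs))


def train_ensemble(X: pd.DataFrame, labels: pd.Series, seed: int = 0,
                   n_trees: int = 500) -> EnsembleModel:
    """Tune and fit the RF / linear-SVM / PLS-DA ensemble.

    Hyperparameter grids: forest features-per-split in {sqrt(D), D/3,
    D/10} at ``n_trees`` trees; SVM cost in {0.01, 0.1, 1, 10}; PLS
    components in 2..10 (capped by dimensionality).  Each is chosen by
    5-fold stratified CV macro one-vs-rest AUC, then refit on all
    training data.  Feature standardization is learned here and frozen
    for external prediction.
    """
    y = pd.Series(labels).reindex(X.index).to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"classes with <5 samples cannot be stratified: {small}")
    scaler = StandardScaler().fit(X.to_numpy(dtype=float))
    Xs = scaler.transform(X.to_numpy(dtype=float))
    d = Xs.shape[1]

    grids = {
        "rf": [
            {"max_features": mf, "n_estimators": n_trees, "random_state": seed}
            for mf in sorted({max(1, int(round(np.sqrt(d)))),
                              max(1, d // 3), max(1, d // 10)})
        ],
        "svm": [
            {"kernel": "linear", "C": c, "probability": True, "random_state": seed}
            for c in (0.01, 0.1, 1.0, 10.0)
        ],
        "plsda": [
            {"n_components": k}
            for k in range(2, min(10, d, len(Xs) - 1) + 1)
        ],
    }
    factories = {"rf": RandomForestClassifier, "svm": SVC, "plsda": PLSDAClassifier}
    classifiers, cv_auc, chosen = {}, {}, {}
    for name, grid in grids.items():
        best_auc, best_params = -np.inf, None
        for params in grid:
            auc = _cv_auc(factories[name](**params), Xs, y, seed)
            if auc > best_auc + 1e-12:
                best_auc, best_params = auc, params
        est = factories[name](**best_params).fit(Xs, y)
        classifiers[name] = est
        cv_auc[name] = best_auc
        chosen[name] = best_params
    return EnsembleModel(classifiers=classifiers, cv_auc=cv_auc, chosen_params=chosen,
                         classes=sorted(np.unique(y), key=str),
                         feature_list=list(X.columns), scaler=scaler)


def predict_clusters(ensemble: EnsembleModel, X_external: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight average of the three classifiers' class probabilities.

    External columns must exactly cover the training feature list (order
    is enforced here).  Assignment is the argmax of the average; exact
    ties go to the lowest class index and are flagged.
    """
    missing = [f for f in ensemble.feature_list if f not in X_external.columns]
    if missing:
        raise ValueError(f"external data missing {len(missing)} training features, "
                         f"e.g. {missing[:5]}")
    Xs = ensemble.scaler.transform(
        X_external[ensemble.feature_list].to_numpy(dtype=float))
    classes = list(ensemble.classes)
    avg = np.zeros((len(Xs), len(classes)))
    for est in ensemble.classifiers.values():
        proba = est.predict_proba(Xs)
        for j, c in enumerate(est.classes_):
            avg[:, classes.index(c)] += proba[:, j]
    avg /= len(ensemble.classifiers)
    assigned_idx = np.argmax(avg, axis=1)  # argmax returns the first (lowest) index on ties
    tie = np.isclose(avg, avg.max(axis=1, keepdims=True), rtol=0, atol=1e-12).sum(axis=1) > 1
    out = pd.DataFrame(avg, index=X_external.index,
                       columns=[f"p_{c}" for c in classes])
    out["assigned"] = [classes[i] for i in assigned_idx]
    out["tie"] = tie
    return out


def build_transfer_matrix(dataset: MultiOmicsDataset, features_per_view: dict,
                          complete_only: bool = True) -> pd.DataFrame:
    """Concatenate the given per-view feature columns into one samples ×
    features frame (complete cases across the used views by default)."""
    blocks = []
    for name, feats in features_per_view.items():
        if not feats:
            continue
        blocks.append(dataset.views[name].to_frame()[feats])
    X = pd.concat(blocks, axis=1)
    if complete_only:
        X = X.dropna()
    return X
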