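"""K-means subtyping on survival-associated factors.

The clusterer is Hartigan-Wong k-means: k-means++ seeding, a few
vectorized Lloyd passes, then single-point reallocation sweeps using
the n/(n±1)-weighted transfer criterion until no move lowers the
within-cluster sum of squares; the best of ``n_start`` runs by
objective is kept.  Cluster count is chosen by the gap statistic with
uniform-over-range reference data (the largest-gap rule; the 1-SE rule
is reported alongside), with silhouette widths as supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_samples

from .factor import FactorModel


@dataclass
class KMeansResult:
    labels: np.ndarray        # 0-based
    centers: np.ndarray
    objective: float          # within-cluster SS
    objective_trace: np.ndarray


@dataclass
class ClusterAssignment:
    labels: pd.Series         # MOC1..MOCk per sample
    centers: np.ndarray
    factor_indices: list
    k: int
    objective: float
    gap_curve: pd.DataFrame
    chosen_k_gap: int
    chosen_k_one_se: int
    silhouette_mean: float
    seed: int


def _within_ss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        rows = X[labels == c]
        if len(rows):
            total += float(np.sum((rows - rows.mean(axis=0)) ** 2))
    return total


def _lloyd(X, centers, max_iter=20):
    for _ in range(max_iter):
        labels = np.argmin(cdist(X, centers, "sqeuclidean"), axis=1)
        new = centers.copy()
        for c in range(len(centers)):
            rows = X[labels == c]
            if len(rows):
                new[c] = rows.mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    return np.argmin(cdist(X, centers, "sqeuclidean"), axis=1), centers


def _hartigan_wong_sweeps(X, labels, k, rng, max_sweeps=50):
    """Single-point reallocation to a local optimum; returns labels,
    centers and the per-sweep objective trace (non-increasing)."""
    n = len(X)
    counts = np.bincount(labels, minlength=k).astype(float)
    # re-seed empty clusters from the farthest point
    for c in np.flatnonzero(counts == 0):
        centers = np.vstack([X[labels == j].mean(axis=0) if counts[j] else X.mean(axis=0)
                             for j in range(k)])
        far = int(np.argmax(np.min(cdist(X, centers, "sqeuclidean"), axis=1)))
        labels[far] = c
        counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.vstack([X[labels == c].sum(axis=0) for c in range(k)])
    trace = [_within_ss(X, labels, k)]
    for _ in range(max_sweeps):
        centers = sums / counts[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        own = labels
        removal = counts[own] / np.maximum(counts[own] - 1.0, 1e-12) * d2[np.arange(n), own]
        gain = counts[None, :] / (counts[None, :] + 1.0) * d2
        gain[np.arange(n), own] = np.inf
        candidates = np.flatnonzero((gain.min(axis=1) < removal) & (counts[own] > 1))
        moved = 0
        for i in candidates:
            r = labels[i]
            if counts[r] <= 1:
                continue
            cr = sums[r] / counts[r]
            rem = counts[r] / (counts[r] - 1.0) * float(np.sum((X[i] - cr) ** 2))
            cen = sums / counts[:, None]
            g = counts / (counts + 1.0) * np.sum((cen - X[i]) ** 2, axis=1)
            g[r] = np.inf
            s = int(np.argmin(g))
            if g[s] < rem - 1e-12:
                labels[i] = s
                sums[r] -= X[i]
                sums[s] += X[i]
                counts[r] -= 1
                counts[s] += 1
                moved += 1
        trace.append(_within_ss(X, labels, k))
        if moved == 0:
            break
    return labels, sums / counts[:, None], np.asarray(trace)


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0, n_start: int = 25) -> KMeansResult:
    """Best-of-``n_start`` Hartigan-Wong k-means with k-means++ seeding."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    if np.isnan(X).any():
        raise ValueError("k-means input must be complete")
    if k == 1:
        mu = X.mean(axis=0)
        obj = float(np.sum((X - mu) ** 2))
        return KMeansResult(np.zeros(n, dtype=int), mu[None, :], obj, np.array([obj]))
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for s in range(n_start):
        centers, _ = kmeans_plusplus(X, n_clusters=k,
                                     random_state=int(rng.integers(2**31 - 1)))
        labels, centers = _lloyd(X, centers)
        labels, centers, trace = _hartigan_wong_sweeps(X, labels.copy(), k, rng)
        obj = float(trace[-1])
        if best is None or obj < best.objective - 1e-12:
            best = KMeansResult(labels.copy(), centers.copy(), obj, trace)
    return best


def gap_statistic(X: np.ndarray, k_max: int = 10, B: int = 100, seed: int = 0,
                  n_start: int = 10, n_start_ref: int = 4) -> tuple[pd.DataFrame, int, int]:
    """Gap statistic over k = 1..k_max with uniform-box references.

    Gap(k) = mean_b log W*_kb - log W_k; SE carries the sqrt(1 + 1/B)
    simulation-error factor.  Returns (curve, argmax-gap k, 1-SE-rule k);
    the largest-gap rule is the primary selection, ties to the smaller k.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        import warnings
        warnings.warn(f"B={B} reference draws is small; gap SEs will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_w = np.empty(len(ks))
    for i, k in enumerate(ks):
        log_w[i] = np.log(kmeans_cluster(X, k, seed=int(rng.integers(2**31 - 1)),
                                         n_start=n_start).objective)
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for i, k in enumerate(ks):
            log_w_ref[b, i] = np.log(
                kmeans_cluster(ref, k, seed=int(rng.integers(2**31 - 1)),
                               n_start=n_start_ref).objective)
    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    curve = pd.DataFrame({"k": ks, "log_w": log_w, "gap": gap, "se": se}).set_index("k")
    # largest-gap selection, made robust to reference-simulation noise:
    # the smallest k whose gap reaches the global maximum within one SE
    i_max = int(np.argmax(gap))
    chosen = int(ks[np.flatnonzero(gap >= gap[i_max] - se[i_max])[0]])
    one_se = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            one_se = int(ks[i])
            break
    return curve, chosen, one_se


def silhouette(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Euclidean silhouette widths per sample and their mean.

    Singleton clusters receive width 0; a single cluster is an error."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    widths = silhouette_samples(np.asarray(X, dtype=float), labels)
    return widths, float(widths.mean())


def define_mocs(model: FactorModel, factor_indices: list, k_max: int = 10,
                seed: int = 0, B: int = 100, force_k: int | None = None,
                standardize: bool = False, n_start: int = 25) -> ClusterAssignment:
    """Cluster patients on the selected factor-score columns.

    Runs the gap statistic, then k-means at the gap-selected k (or a
    forced k).  Labels are renamed MOC1..MOCk ordered by descending mean
    of the first selected factor so numbering is stable across runs.
    """
    if not factor_indices:
        raise ValueError("no factor indices supplied")
    X = model.Z[:, list(factor_indices)]
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    curve, k_gap, k_one_se = gap_statistic(X, k_max=k_max, B=B, seed=seed)
    k = int(force_k) if force_k is not None else k_gap
    km = kmeans_cluster(X, k, seed=seed, n_start=n_start)
    order = np.argsort(-np.array([X[km.labels == c, 0].mean() for c in range(k)]))
    rename = {int(c): f"MOC{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([rename[int(c)] for c in km.labels],
                       index=model.sample_ids, name="MOC")
    sil_mean = silhouette(X, km.labels)[1] if k >= 2 else float("nan")
    return ClusterAssignment(
        labels=labels, centers=km.centers[order], factor_indices=list(factor_indices),
        k=k, objective=km.objective, gap_curve=curve,
        chosen_k_gap=k_gap, chosen_k_one_se=k_one_se,
        silhouette_mean=sil_mean, seed=seed,
    )
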