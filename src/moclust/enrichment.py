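"""Signal-to-noise gene ranking and gene-set enrichment analysis.

Genes are ranked between two phenotype groups by the signal-to-noise
ratio (mu_A - mu_B) / (sigma_A + sigma_B).  Enrichment of a gene set is
the signed extremum of the weighted Kolmogorov-Smirnov running sum over
the ranked list (hits weighted by |score|^p, misses by the uniform
decrement).  Significance comes from phenotype-label permutations with
re-ranking; NES divides the observed score by the mean same-sign
permuted score, and the FDR is the canonical ratio of pooled-null to
observed NES tail fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt


@dataclass
class RankedList:
    features: list      # ordered by score descending, ties by feature id
    scores: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("ranked list must be sorted descending")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list


def read_gene_sets(path) -> dict:
    """Read GMT gene sets (name, description, members per line)."""
    sets = _read_gmt(str(path))
    return {k: list(dict.fromkeys(v)) for k, v in sets.items()}


def write_gene_sets(sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def _snr_scores(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Signal-to-noise per feature column with the standard SD floor
    max(sigma, 0.2 |mu|, 0.2) applied per group."""
    mu_a, mu_b = X[mask_a].mean(axis=0), X[mask_b].mean(axis=0)
    sd_a = X[mask_a].std(axis=0, ddof=1)
    sd_b = X[mask_b].std(axis=0, ddof=1)
    sd_a = np.maximum.reduce([sd_a, 0.2 * np.abs(mu_a), np.full_like(sd_a, 0.2)])
    sd_b = np.maximum.reduce([sd_b, 0.2 * np.abs(mu_b), np.full_like(sd_b, 0.2)])
    return (mu_a - mu_b) / (sd_a + sd_b)


def snr_rank(X: pd.DataFrame, group_a: list, group_b: list) -> RankedList:
    """Rank features by signal-to-noise between two sample groups."""
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("phenotype groups overlap")
    mask_a = X.index.isin(set_a)
    mask_b = X.index.isin(set_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least two samples per group")
    scores = _snr_scores(X.to_numpy(dtype=float), mask_a, mask_b)
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], str(X.columns[i])))
    return RankedList(features=[X.columns[i] for i in order],
                      scores=scores[np.asarray(order)])


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0
                     ) -> tuple[float, np.ndarray, list]:
    """Weighted KS running sum: returns (ES, running sum, leading edge).

    Hits increment by |score|^weight normalized over hits; misses
    decrement by 1/(N - N_hits).  ES is the running sum's signed
    extremum; the leading edge holds the members up to the extremum
    (positive ES) or after it (negative ES).
    """
    members = set(gene_set)
    hit = np.array([f in members for f in ranked.features])
    n_hits = int(hit.sum())
    n = len(hit)
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hits == n:
        raise ValueError("misses empty: gene set covers the entire ranked list")
    w = np.abs(ranked.scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hit.astype(float)
        denom = float(n_hits)
    steps = w_hit / denom - (~hit) / float(n - n_hits)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [f for f, h in zip(ranked.features[:i_ext + 1], hit[:i_ext + 1]) if h]
    else:
        leading = [f for f, h in zip(ranked.features[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def gsea(X: pd.DataFrame, labels: pd.Series, gene_sets: dict,
         n_perm: int = 1000, size_range: tuple = (15, 500),
         weight: float = 1.0, fdr_cut: float = 0.25,
         seed: int = 0) -> pd.DataFrame:
    """Phenotype-permutation GSEA between two groups.

    Sets are filtered to ``size_range`` after intersection with the
    measured features.  Returns a table (one row per retained set) with
    ES, NES, nominal p (one-sided on the matching sign, +1 corrected),
    FDR q and a pass flag at ``fdr_cut``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = pd.Series(labels).reindex(X.index)
    classes = sorted(labels.dropna().unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two phenotype groups, got {classes}")
    measured = set(X.columns)
    filtered = {}
    for name, members in gene_sets.items():
        inter = [m for m in members if m in measured]
        if size_range[0] <= len(inter) <= size_range[1]:
            filtered[name] = inter
    if not filtered:
        raise ValueError("all gene sets removed by the size filter")

    mask_a = (labels == classes[0]).to_numpy()
    mask_b = (labels == classes[1]).to_numpy()
    Xv = X.to_numpy(dtype=float)
    cols = list(X.columns)
    col_index = {c: i for i, c in enumerate(cols)}
    # lexicographic tie-break rank per feature id (deterministic ordering)
    tie_rank = np.empty(len(cols), dtype=int)
    tie_rank[np.argsort(np.asarray(cols, dtype=str), kind="stable")] = np.arange(len(cols))
    set_masks = {}
    for name, members in filtered.items():
        m = np.zeros(len(cols), dtype=bool)
        m[[col_index[f] for f in members]] = True
        set_masks[name] = m

    def _order(scores):
        return np.lexsort((tie_rank, -scores))

    def _es_fast(scores, order, mask):
        hit = mask[order]
        w = np.abs(scores[order]) ** weight
        w_hit = np.where(hit, w, 0.0)
        denom = w_hit.sum()
        if denom == 0:
            w_hit = hit.astype(float)
            denom = float(hit.sum())
        running = np.cumsum(w_hit / denom - (~hit) / float(len(hit) - hit.sum()))
        return float(running[np.argmax(np.abs(running))])

    _sc = _snr_scores(Xv, mask_a, mask_b)
    _ord = _order(_sc)
    observed = RankedList(features=[cols[i] for i in _ord], scores=_sc[_ord])
    obs = {name: enrichment_score(observed, members, weight)
           for name, members in filtered.items()}

    rng = np.random.default_rng(seed)
    n_a = int(mask_a.sum())
    usable = np.flatnonzero(mask_a | mask_b)
    null_es = {name: np.empty(n_perm) for name in filtered}
    for b in range(n_perm):
        perm = rng.permutation(usable)
        m1 = np.zeros(len(labels), dtype=bool)
        m1[perm[:n_a]] = True
        m2 = np.zeros(len(labels), dtype=bool)
        m2[perm[n_a:]] = True
        scores = _snr_scores(Xv, m1, m2)
        order = _order(scores)
        for name, mask in set_masks.items():
            null_es[name][b] = _es_fast(scores, order, mask)

    rows = []
    nes_obs, nes_null_pool = {}, []
    for name in filtered:
        es = obs[name][0]
        null = null_es[name]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        mean_same = np.mean(np.abs(same)) if len(same) else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        nes_obs[name] = nes
        with np.errstate(invalid="ignore", divide="ignore"):
            pos_mean = np.mean(null[null >= 0]) if np.any(null >= 0) else np.nan
            neg_mean = np.mean(np.abs(null[null < 0])) if np.any(null < 0) else np.nan
        nn = np.where(null >= 0,
                      null / pos_mean if np.isfinite(pos_mean) else np.nan,
                      null / neg_mean if np.isfinite(neg_mean) else np.nan)
        nes_null_pool.append(nn[np.isfinite(nn)])
        if es >= 0:
            p = (1 + int(np.sum(null >= es))) / (1 + max(len(same), 1))
        else:
            p = (1 + int(np.sum(null <= es))) / (1 + max(len(same), 1))
        rows.append((name, es, nes, min(p, 1.0)))

    pool = np.concatenate(nes_null_pool) if nes_null_pool else np.array([])
    all_nes = np.array([nes_obs[name] for name, *_ in rows])
    results = []
    for (name, es, nes, p) in rows:
        if not np.isfinite(nes) or len(pool) == 0:
            fdr = 1.0
        elif nes >= 0:
            num = np.mean(pool >= nes) if np.any(pool >= 0) else 0.0
            den = np.mean(all_nes[np.isfinite(all_nes)] >= nes)
            fdr = min(num / den, 1.0) if den > 0 else 1.0
        else:
            num = np.mean(pool <= nes)
            den = np.mean(all_nes[np.isfinite(all_nes)] <= nes)
            fdr = min(num / den, 1.0) if den > 0 else 1.0
        results.append({
            "set": name, "es": es, "nes": nes, "p": p, "fdr": fdr,
            "size": len(filtered[name]),
            "leading_edge": "|".join(map(str, obs[name][2])),
            "significant": fdr < fdr_cut,
        })
    return pd.DataFrame(results).set_index("set").sort_values("p")
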