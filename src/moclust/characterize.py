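"""Factor-clinical associations, per-feature cluster tests and summary tables.

Association tests follow the usual nonparametric toolbox: Spearman rank
correlation for ordinal/continuous variables, Wilcoxon rank-sum for
binary groupings, Kruskal-Wallis for three or more groups, each family
Benjamini-Hochberg adjusted.  Stratified clinical summaries reproduce
the count (percent) layout of cohort-characteristics tables; percent
denominators include NA rows and rounding is half-away-from-zero to one
decimal.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CLINICAL_CATEGORIES, MultiOmicsDataset
from .factor import FactorModel

_ORDINAL = {
    "grade": ["I", "II", "III", "IV"],
    "node_status": ["pN0", "pN1mi", "pN1", "pN2", "pN3"],
    "tumor_stage": ["pTis", "pT1", "pT2", "pT3", "pT4"],
}
_BINARY = ["er", "pr", "her2", "tnbc", "histology_ductal", "size_gt20mm"]


def dichotomize_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derived binary columns: ductal vs non-ductal histology and tumor
    size </> 20 mm (falling back to stage: pTis/pT1 -> <=20 mm, pT2+ ->
    >20 mm when the measured size is missing).  NA propagates."""
    out = clinical.copy()
    if "histology" in out.columns:
        # any named non-ductal histology (lobular, mucinous, ...) counts as
        # non-ductal; only missing stays missing
        out["histology_ductal"] = np.where(
            out["histology"].isin(["NA", None]) | out["histology"].isna(), "NA",
            np.where(out["histology"] == "ductal", "yes", "no"))
    size = pd.to_numeric(
        out["tumor_size_mm"] if "tumor_size_mm" in out.columns
        else pd.Series(np.nan, index=out.index), errors="coerce")
    stage = (out["tumor_stage"] if "tumor_stage" in out.columns
             else pd.Series("NA", index=out.index))
    by_stage = stage.map({"pTis": "no", "pT1": "no", "pT2": "yes",
                          "pT3": "yes", "pT4": "yes"}).fillna("NA")
    by_size = pd.Series(
        np.where(size.notna(), np.where(size > 20, "yes", "no"), None),
        index=out.index)
    out["size_gt20mm"] = by_size.fillna(by_stage).fillna("NA")
    return out


def factor_clinical_association(model: FactorModel,
                                clinical: pd.DataFrame) -> pd.DataFrame:
    """Test every factor against every clinical variable.

    Returns a long table (factor, variable, test, statistic, p, p_bh)
    with BH adjustment within each variable family.  Groups with fewer
    than two samples are skipped with a note in the ``note`` column.
    """
    clin = dichotomize_clinical(clinical).set_index("sample_id")
    clin = clin.reindex(model.sample_ids)
    scores = model.factor_scores()
    rows = []
    for var, levels in _ORDINAL.items():
        if var not in clin.columns:
            continue
        ordv = clin[var].map({lv: i for i, lv in enumerate(levels)})
        ok = ordv.notna()
        for f in scores.columns:
            rho, p = stats.spearmanr(scores.loc[ok.values, f], ordv[ok])
            rows.append((f, var, "spearman", rho, p, ""))
    for var in _BINARY + ["subtype_label"]:
        if var not in clin.columns:
            continue
        vals = clin[var].replace("NA", np.nan).dropna()
        groups = [scores.loc[vals.index[vals == g], :] for g in sorted(vals.unique(), key=str)]
        if len(groups) < 2:
            continue
        for f in scores.columns:
            samples = [g[f].to_numpy() for g in groups]
            sizes = [len(s) for s in samples]
            if min(sizes) < 2:
                rows.append((f, var, "skipped", np.nan, np.nan,
                             f"group with <2 samples (sizes {sizes})"))
                continue
            if len(samples) == 2:
                stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                             alternative="two-sided")
                rows.append((f, var, "wilcoxon", stat, p, ""))
            else:
                stat, p = stats.kruskal(*samples)
                rows.append((f, var, "kruskal_wallis", stat, p, ""))
    df = pd.DataFrame(rows, columns=["factor", "variable", "test",
                                     "statistic", "p", "note"])
    df["p_bh"] = np.nan
    for var in df["variable"].unique():
        sel = (df["variable"] == var) & df["p"].notna()
        if sel.any():
            df.loc[sel, "p_bh"] = multipletests(df.loc[sel, "p"], method="fdr_bh")[1]
    return df


def spearman_matrix(model: FactorModel, clinical: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between each factor and each ordinal/continuous variable."""
    clin = dichotomize_clinical(clinical).set_index("sample_id").reindex(model.sample_ids)
    scores = model.factor_scores()
    cols = {}
    for var, levels in _ORDINAL.items():
        if var in clin.columns:
            cols[var] = clin[var].map({lv: i for i, lv in enumerate(levels)})
    for var in ("age", "tumor_size_mm"):
        if var in clin.columns:
            cols[var] = pd.to_numeric(clin[var], errors="coerce")
    out = pd.DataFrame(index=scores.columns, columns=list(cols), dtype=float)
    for var, v in cols.items():
        ok = v.notna().to_numpy()
        for f in scores.columns:
            out.loc[f, var] = stats.spearmanr(scores.loc[ok, f], v[ok])[0]
    return out


def feature_cluster_tests(dataset: MultiOmicsDataset,
                          labels: pd.Series) -> dict:
    """Per-feature Kruskal-Wallis across clusters, BH-adjusted per view.

    Returns view -> table (feature, p, p_bh, per-cluster medians).
    Features observed in fewer than two clusters are skipped."""
    labels = labels.reindex(dataset.sample_ids)
    clusters = sorted(labels.dropna().unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    out = {}
    for name, view in dataset.views.items():
        frame = view.to_frame()
        rows = []
        for feat in frame.columns:
            col = frame[feat]
            samples, medians = [], {}
            for c in clusters:
                vals = col[(labels == c).values].dropna().to_numpy()
                if len(vals):
                    samples.append(vals)
                medians[c] = float(np.median(vals)) if len(vals) else np.nan
            if len(samples) < 2:
                continue
            if np.ptp(np.concatenate(samples)) == 0:
                p = 1.0  # every rank tied
            else:
                _, p = stats.kruskal(*samples)
            rows.append({"feature": feat, "p": p,
                         **{f"median_{c}": medians[c] for c in clusters}})
        table = pd.DataFrame(rows)
        if len(table):
            table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
        out[name] = table
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def contingency_summary(clinical: pd.DataFrame, strata: pd.Series,
                        variables: list | None = None) -> pd.DataFrame:
    """Count (percent) table per stratum and variable category.

    Percent = 100 * count / stratum size (NA rows included in the
    denominator), rounded half-away-from-zero to one decimal."""
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    strata = strata.reindex(clin.index)
    if strata.isna().any():
        raise ValueError("strata must cover all samples")
    if variables is None:
        variables = [c for c in CLINICAL_CATEGORIES if c in clin.columns]
        variables += [c for c in ("subtype_label",) if c in clin.columns]
    rows = []
    for s in sorted(strata.unique(), key=str):
        members = clin[(strata == s).values]
        n = len(members)
        for var in variables:
            levels = CLINICAL_CATEGORIES.get(var)
            observed = members[var].astype(str)
            cats = levels if levels else sorted(observed.unique(), key=str)
            for cat in cats:
                count = int((observed == cat).sum())
                pct = _round_half_up(100.0 * count / n) if n else 0.0
                rows.append((str(s), n, var, cat, count, pct))
    return pd.DataFrame(rows, columns=["stratum", "stratum_size", "variable",
                                       "category", "count", "percent"])
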