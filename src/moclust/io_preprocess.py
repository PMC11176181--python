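"""Matrix/table readers and writers, transcript preprocessing, dataset assembly.

File conventions: sample × feature matrices as delimited text with the
first column holding sample ids and the header row feature ids; empty
cells are missing values.  Clinical and survival tables are plain CSV.
All writers emit UTF-8 CSV with a fixed column order so round-trips are
deterministic.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datasets import (
    MultiOmicsDataset,
    OmicsView,
    _first_duplicate,
    validate_clinical,
    validate_outcomes,
)

log = logging.getLogger(__name__)


def read_view(path, name: str, sep: str = ",", log2: bool = False) -> OmicsView:
    """Read a sample × feature matrix into an :class:`OmicsView`.

    Empty cells become NaN; a sample whose entire row is empty gets
    ``observed=False``.  ``log2=True`` applies log2(x+1) at read time
    for raw-scale transcript matrices.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    for kind, ids in (("sample", sample_ids), ("feature", feature_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"{path}: duplicate {kind} id {dup!r}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)  # exact strtod round-trip
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell at row {sample_ids[i]!r}, "
                    f"column {feature_ids[j]!r}: {cell!r}"
                ) from exc
    if log2:
        values = np.log2(values + 1.0)
    observed = ~np.isnan(values).all(axis=1)
    values[~observed] = np.nan
    return OmicsView(name, sample_ids, feature_ids, values, observed)


def write_view(view: OmicsView, path) -> None:
    """Write a view as CSV; unobserved rows become empty cells.

    Floats are written with shortest round-tripping repr, so
    ``read_view(write_view(v))`` reproduces values bit-exactly.
    """
    frame = view.to_frame()
    as_text = frame.map(lambda x: "" if pd.isna(x) else repr(float(x)))
    as_text.to_csv(path, na_rep="")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False, na_values=[""])
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].fillna("NA")
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    lead = [c for c in ["sample_id", "age"] if c in clinical.columns]
    rest = sorted(c for c in clinical.columns if c not in lead)
    clinical[lead + rest].to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_outcomes(df)


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    outcomes[["sample_id", "time", "event", "endpoint"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transcript preprocessing


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a feature × sample block.

    Every column is mapped onto the across-column means of the order
    statistics, so all columns share one empirical distribution.  Ties
    within a column receive the mean of their target quantile values.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires complete data; mask afterwards")
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        vals = target.copy()
        # average target values across tied runs
        i = 0
        n = len(col_sorted)
        while i < n:
            k = i + 1
            while k < n and col_sorted[k] == col_sorted[i]:
                k += 1
            if k - i > 1:
                vals[i:k] = vals[i:k].mean()
            i = k
        out[order, j] = vals
    return out


def collapse_probes(values: np.ndarray, probe_ids: list[str],
                    probe_to_gene: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Average probe rows mapping to the same gene (samples in columns).

    Output gene order is first-appearance order of the genes among the
    probes.  Every probe must be mapped.
    """
    unmapped = [p for p in probe_ids if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"unmapped probes: {unmapped[:5]}")
    x = np.asarray(values, dtype=float)
    if x.shape[0] != len(probe_ids):
        raise ValueError("values rows must match probe_ids")
    genes: list[str] = []
    index: dict[str, int] = {}
    for p in probe_ids:
        g = probe_to_gene[p]
        if g not in index:
            index[g] = len(genes)
            genes.append(g)
    out = np.zeros((len(genes), x.shape[1]))
    counts = np.zeros(len(genes))
    for i, p in enumerate(probe_ids):
        gi = index[probe_to_gene[p]]
        out[gi] += x[i]
        counts[gi] += 1
    return out / counts[:, None], genes


def batch_center(values: np.ndarray, batch: list[str]) -> np.ndarray:
    """Location-only batch adjustment of a samples × features matrix.

    Within each batch every feature's batch mean is removed, then the
    global feature mean is added back, so per-feature global means are
    preserved and only between-batch location shifts are corrected.
    """
    x = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    if batch.shape[0] != x.shape[0]:
        raise ValueError("one batch label per sample required")
    global_mean = np.nanmean(x, axis=0)
    out = x.copy()
    for b in np.unique(batch):
        rows = batch == b
        out[rows] = x[rows] - np.nanmean(x[rows], axis=0) + global_mean
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble_dataset(views: list[OmicsView], clinical: pd.DataFrame,
                     outcomes: pd.DataFrame) -> MultiOmicsDataset:
    """Align views onto one master roster and attach clinical/outcomes.

    Master roster = union of the view rosters intersected with the
    clinical sample ids, in clinical-table order.  Views are reindexed
    to the roster; samples a view never measured get all-missing rows
    with ``observed=False``.  Clinical samples present in no view are
    dropped with a warning.
    """
    validate_clinical(clinical)
    view_union: set[str] = set()
    for v in views:
        view_union |= set(v.sample_ids)
    clin_ids = [str(s) for s in clinical["sample_id"]]
    roster = [s for s in clin_ids if s in view_union]
    if not roster:
        raise ValueError("no overlap between view sample ids and clinical sample ids")
    dropped = [s for s in clin_ids if s not in view_union]
    if dropped:
        warnings.warn(
            f"{len(dropped)} clinical samples observed in no view were excluded "
            f"(e.g. {dropped[:3]})",
            stacklevel=2,
        )
    roster_set = set(roster)
    aligned: dict[str, OmicsView] = {}
    for v in views:
        frame = v.to_frame()
        obs = pd.Series(v.observed, index=v.sample_ids)
        frame = frame.reindex(roster)
        observed = np.array([bool(obs.get(s, False)) for s in roster])
        vals = frame.to_numpy(dtype=float)
        vals[~observed] = np.nan
        aligned[v.name] = OmicsView(v.name, roster, list(v.feature_ids), vals, observed)
        log.info("view %s: %d/%d samples observed", v.name, int(observed.sum()), len(roster))
    clin = clinical[clinical["sample_id"].astype(str).isin(roster_set)].reset_index(drop=True)
    clin = clin.set_index("sample_id").loc[roster].reset_index()
    out = outcomes[outcomes["sample_id"].astype(str).isin(roster_set)].reset_index(drop=True)
    return MultiOmicsDataset(views=aligned, clinical=clin, outcomes=out, sample_ids=roster)
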