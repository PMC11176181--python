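"""Core containers for aligned multi-omics cohorts.

A cohort is a collection of per-view (per-platform) sample × feature
matrices sharing one master sample roster, a clinical table and
time-to-event outcomes.  Each view carries a per-sample ``observed``
flag: missingness is modelled at whole-sample-per-view granularity
(a patient either was or was not profiled on a platform), which is how
per-platform availability arises in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRADE_LEVELS = ["I", "II", "III", "IV", "NA"]
NODE_LEVELS = ["pN0", "pN1mi", "pN1", "pN2", "pN3", "NA"]
STAGE_LEVELS = ["pTis", "pT1", "pT2", "pT3", "pT4", "NA"]
HISTOLOGY_LEVELS = ["ductal", "non-ductal", "NA"]
RECEPTOR_LEVELS = ["pos", "neg", "NA"]
YESNO_LEVELS = ["yes", "no", "NA"]
ENDPOINTS = [
    "all_cause",
    "bc_specific",
    "bc_death_or_metastasis",
    "bc_death_metastasis_or_relapse",
]

#: categorical clinical columns and their admissible levels
CLINICAL_CATEGORIES: dict[str, list[str]] = {
    "grade": GRADE_LEVELS,
    "node_status": NODE_LEVELS,
    "tumor_stage": STAGE_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "er": RECEPTOR_LEVELS,
    "pr": RECEPTOR_LEVELS,
    "her2": RECEPTOR_LEVELS,
    "tnbc": YESNO_LEVELS,
}


@dataclass
class OmicsView:
    """One omics layer: values, ids and a per-sample presence flag.

    ``values`` is samples × features.  Rows with ``observed=False``
    contain only NaN; observed rows may not be entirely NaN.
    """

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    observed: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError(
                f"view {self.name!r}: matrix {self.values.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"view {self.name!r}: duplicate {kind} id {dup!r}")
        if self.observed.shape != (n,):
            raise ValueError(f"view {self.name!r}: observed flag length mismatch")
        row_all_nan = np.isnan(self.values).all(axis=1) if d else np.ones(n, bool)
        if d and np.any(~row_all_nan[~self.observed]):
            raise ValueError(f"view {self.name!r}: unobserved rows must be all-missing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def _first_duplicate(ids) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table schema and category levels; returns the table.

    Required: ``sample_id``.  Categorical columns listed in
    :data:`CLINICAL_CATEGORIES` are restricted to their level sets
    (missing encoded as the literal string ``"NA"``); ``age`` must be
    positive where present.
    """
    if "sample_id" not in clinical.columns:
        raise ValueError("clinical table must have a 'sample_id' column")
    dup = _first_duplicate(list(clinical["sample_id"]))
    if dup is not None:
        raise ValueError(f"clinical table: duplicate sample_id {dup!r}")
    for col, levels in CLINICAL_CATEGORIES.items():
        if col in clinical.columns:
            bad = set(clinical[col].dropna().astype(str)) - set(levels)
            if bad:
                raise ValueError(f"clinical column {col!r}: invalid levels {sorted(bad)}")
    if "age" in clinical.columns:
        age = pd.to_numeric(clinical["age"], errors="coerce")
        if (age.dropna() <= 0).any():
            raise ValueError("clinical column 'age': ages must be positive")
    return clinical


def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Check survival-outcome records: positive times, binary events,
    known endpoint names, one record per (sample, endpoint)."""
    required = {"sample_id", "time", "event", "endpoint"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    if (outcomes["time"] <= 0).any():
        raise ValueError("outcome times must be strictly positive")
    if not outcomes["event"].isin([0, 1]).all():
        raise ValueError("outcome event indicator must be 0/1")
    bad = set(outcomes["endpoint"]) - set(ENDPOINTS)
    if bad:
        raise ValueError(f"unknown endpoints: {sorted(bad)}")
    if outcomes.duplicated(["sample_id", "endpoint"]).any():
        raise ValueError("duplicate (sample_id, endpoint) outcome records")
    return outcomes


@dataclass
class MultiOmicsDataset:
    """Aligned multi-view cohort.

    Every view's row order equals ``sample_ids`` (the master roster);
    every sample is observed in at least one view.
    """

    views: dict[str, OmicsView]
    clinical: pd.DataFrame
    outcomes: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            first = next(iter(self.views.values()))
            self.sample_ids = list(first.sample_ids)
        for v in self.views.values():
            if list(v.sample_ids) != list(self.sample_ids):
                raise ValueError(f"view {v.name!r} roster differs from master roster")
        validate_clinical(self.clinical)
        validate_outcomes(self.outcomes)
        obs_any = np.zeros(len(self.sample_ids), dtype=bool)
        for v in self.views.values():
            obs_any |= v.observed
        if not obs_any.all():
            orphans = [s for s, ok in zip(self.sample_ids, obs_any) if not ok]
            raise ValueError(f"samples observed in no view: {orphans[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def observed_counts(self) -> dict[str, int]:
        return {name: int(v.observed.sum()) for name, v in self.views.items()}

    def subset(self, keep_ids: list) -> "MultiOmicsDataset":
        """Restrict the cohort to a sample subset (roster order preserved)."""
        keep = [s for s in self.sample_ids if s in set(keep_ids)]
        if not keep:
            raise ValueError("subset would be empty")
        idx = [self.sample_ids.index(s) for s in keep]
        views = {
            name: OmicsView(v.name, keep, list(v.feature_ids),
                            v.values[idx], v.observed[idx])
            for name, v in self.views.items()
        }
        clin = self.clinical[self.clinical["sample_id"].isin(set(keep))].reset_index(drop=True)
        out = self.outcomes[self.outcomes["sample_id"].isin(set(keep))].reset_index(drop=True)
        return MultiOmicsDataset(views=views, clinical=clin, outcomes=out, sample_ids=keep)

    def outcome(self, endpoint: str) -> pd.DataFrame:
        """Outcome records for one endpoint, indexed by sample_id."""
        sub = self.outcomes[self.outcomes["endpoint"] == endpoint]
        return sub.set_index("sample_id").loc[
            [s for s in self.sample_ids if s in set(sub["sample_id"])]
        ]
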