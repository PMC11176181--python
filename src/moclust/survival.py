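"""Cox proportional-hazards screening, Kaplan-Meier curves and log-rank tests.

Cox fits use the Efron partial likelihood (the sensible default for
event times recorded in months, where ties are common).  The factor
screen fits one multivariate Cox model over all factor scores (crude)
and one adding age, and selects factors whose crude Wald p-value clears
alpha.  The proportional-hazards diagnostic is a Grambsch-Therneau
style test on scaled Schoenfeld residuals against Kaplan-Meier
transformed event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .factor import FactorModel


@dataclass
class CoxFit:
    covariates: list
    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame          # columns lo, hi (hazard-ratio scale)
    wald_p: pd.Series
    lrt_p: float
    log_likelihood: float
    ties: str
    n: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) and (s[0] > 1 + 1e-12 or np.any(np.diff(s) > 1e-12)
                       or np.any(s < -1e-12) or np.any(s > 1 + 1e-12)):
            raise ValueError("survival curve must start at 1, be non-increasing, in [0,1]")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")


def truncate_follow_up(outcome: pd.DataFrame, months: float) -> pd.DataFrame:
    """Administratively censor all follow-up at a horizon (e.g. 15 years
    = 180 months): later events become censorings at the horizon."""
    if months <= 0:
        raise ValueError("truncation horizon must be positive")
    out = outcome.copy()
    late = out["time"] > months
    out.loc[late, "time"] = months
    out.loc[late, "event"] = 0
    return out


def fit_cox(X: pd.DataFrame, outcome: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Fit a (multivariate) Cox model of `outcome` (time, event) on X.

    Complete-case: rows with missing covariates are dropped with a
    warning.  Raises on zero events or a monotone likelihood.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    df = pd.concat([X, outcome[["time", "event"]]], axis=1, join="inner")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} rows with missing covariates",
                      stacklevel=2)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the outcome data")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(
            "Cox partial likelihood is monotone (complete separation); "
            "consider penalization"
        ) from exc
    summ = cph.summary
    ci = pd.DataFrame({
        "lo": np.exp(summ["coef lower 95%"]),
        "hi": np.exp(summ["coef upper 95%"]),
    })
    lrt = cph.log_likelihood_ratio_test()
    return CoxFit(
        covariates=list(summ.index),
        beta=summ["coef"],
        se=summ["se(coef)"],
        hr=np.exp(summ["coef"]),
        ci95=ci,
        wald_p=summ["p"],
        lrt_p=float(lrt.p_value),
        log_likelihood=float(cph.log_likelihood_),
        ties="efron",
        n=len(df),
        n_events=n_events,
        fitter=cph,
        data=df,
    )


def schoenfeld_test(fit: CoxFit) -> pd.DataFrame:
    """Proportional-hazards diagnostic from scaled Schoenfeld residuals.

    Scaled residuals are regressed (score-test style) against
    g(t) = 1 - KM(t) at the event times; per-covariate chi-square tests
    plus a global test (df = number of covariates) are returned in a
    table with rows per covariate and a final ``GLOBAL`` row.
    """
    df = fit.data
    d = int(df["event"].sum())
    if d < 3:
        raise ValueError("need at least 3 events for the PH diagnostic")
    resid = fit.fitter.compute_residuals(df, "scaled_schoenfeld")
    resid = resid.sort_index()
    event_rows = df[df["event"] == 1].sort_index()
    times = event_rows.loc[resid.index, "time"].to_numpy()
    order = np.argsort(times, kind="stable")
    times = times[order]
    R = resid.to_numpy()[order]

    km = KaplanMeierFitter().fit(df["time"], df["event"])
    surv = km.survival_function_["KM_estimate"]
    g = 1.0 - np.asarray([float(surv.loc[:t].iloc[-1]) for t in times])
    gc = g - g.mean()
    gg = float(np.sum(gc ** 2))

    p_cov = fit.fitter.variance_matrix_.to_numpy()   # I^{-1}(beta)
    u = gc @ R                                       # per-covariate score
    # scaled residuals are d * I^{-1} s_k; Var(sum gc*s*) ~ gg * d * I^{-1}
    rows = []
    for j, name in enumerate(resid.columns):
        chi2 = u[j] ** 2 / (gg * d * p_cov[j, j])
        rows.append((name, chi2, 1, float(stats.chi2.sf(chi2, 1))))
    prec = np.linalg.inv(p_cov)
    chi2_g = float(u @ prec @ u) / (gg * d)
    rows.append(("GLOBAL", chi2_g, len(resid.columns),
                 float(stats.chi2.sf(chi2_g, len(resid.columns)))))
    return pd.DataFrame(rows, columns=["covariate", "chi2", "df", "p"]).set_index("covariate")


def select_survival_factors(model: FactorModel, outcome: pd.DataFrame,
                            clinical: pd.DataFrame | None = None,
                            alpha: float = 0.05) -> tuple[list, CoxFit, CoxFit | None]:
    """Screen factors by crude multivariate Cox Wald p < alpha.

    Returns (selected 0-based factor indices, crude fit, age-adjusted
    fit or None).  The age-adjusted model is reported for robustness;
    selection uses the crude Wald p-values.
    """
    scores = model.factor_scores()
    out = outcome.copy()
    if "sample_id" in out.columns:
        out = out.set_index("sample_id")
    common = [s for s in scores.index if s in out.index]
    X = scores.loc[common]
    crude = fit_cox(X, out.loc[common])
    adjusted = None
    if clinical is not None and "age" in clinical.columns:
        ages = clinical.set_index("sample_id")["age"]
        Xa = X.copy()
        Xa["age"] = pd.to_numeric(ages.reindex(common), errors="coerce")
        adjusted = fit_cox(Xa, out.loc[common])
    selected = [int(c[1:]) - 1 for c in crude.covariates if crude.wald_p[c] < alpha]
    return selected, crude, adjusted


def kaplan_meier(outcome: pd.DataFrame, groups: pd.Series,
                 time_grid: np.ndarray | None = None
                 ) -> tuple[dict, pd.DataFrame]:
    """Product-limit curves per group plus a risk table on a time grid."""
    out = outcome.copy()
    if "sample_id" in out.columns:
        out = out.set_index("sample_id")
    groups = groups.reindex(out.index)
    curves: dict[str, KMCurve] = {}
    if time_grid is None:
        tmax = float(out["time"].max())
        time_grid = np.linspace(0.0, tmax, 6)
    risk_rows = {}
    for g in sorted(groups.dropna().unique(), key=str):
        rows = out[groups == g]
        if len(rows) == 0:
            warnings.warn(f"group {g!r} empty; skipped", stacklevel=2)
            continue
        km = KaplanMeierFitter().fit(rows["time"], rows["event"], label=str(g))
        sf = km.survival_function_[str(g)]
        ev = km.event_table
        curves[str(g)] = KMCurve(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=float),
            censor_times=rows.loc[rows["event"] == 0, "time"].to_numpy(),
        )
        risk_rows[str(g)] = [int((rows["time"] >= t).sum()) for t in time_grid]
    risk_table = pd.DataFrame(risk_rows, index=np.round(time_grid, 3)).T
    risk_table.index.name = "group"
    return curves, risk_table


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None   # columns p, p_bh


def logrank_test(outcome: pd.DataFrame, groups: pd.Series,
                 pairwise: bool = False) -> LogrankResult:
    """k-group log-rank test; optional pairwise matrix.

    Pairwise p-values are reported unadjusted (as in standard survival
    figures) with BH-adjusted copies alongside.
    """
    out = outcome.copy()
    if "sample_id" in out.columns:
        out = out.set_index("sample_id")
    g = groups.reindex(out.index).dropna()
    out = out.loc[g.index]
    labels = g.astype(str)
    if labels.nunique() < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    res = multivariate_logrank_test(out["time"], labels, out["event"])
    pw = None
    if pairwise:
        raw = pairwise_logrank_test(out["time"], labels, out["event"]).summary
        pvals = raw["p"].to_numpy()
        adj = multipletests(pvals, method="fdr_bh")[1]
        pw = pd.DataFrame({"p": pvals, "p_bh": adj}, index=raw.index)
    return LogrankResult(chi2=float(res.test_statistic),
                         df=int(labels.nunique() - 1),
                         p=float(res.p_value), pairwise=pw)
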