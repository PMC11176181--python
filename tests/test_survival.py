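import numpy as np
import pandas as pd
import pytest

from moclust import fit_cox, kaplan_meier, logrank_test, select_survival_factors
from moclust.survival import schoenfeld_test


def _outcome(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events,
                         "endpoint": "all_cause"})


def brute_logrank(time, event, group):
    """Independent k-group log-rank via hypergeometric moments."""
    groups = sorted(set(group))
    k = len(groups)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n = at.sum()
        d = ((time == t) & (event == 1)).sum()
        for i, g in enumerate(groups):
            ni = (at & (group == g)).sum()
            di = ((time == t) & (event == 1) & (group == g)).sum()
            O[i] += di
            E[i] += d * ni / n
            for j, h in enumerate(groups):
                nj = (at & (group == h)).sum()
                if n > 1:
                    V[i, j] += d * (n - d) / (n - 1) * (
                        (ni / n) * ((i == j) - nj / n))
    z = (O - E)[:-1]
    return float(z @ np.linalg.solve(V[:-1, :-1], z))


def cox_score_statistic(time, event, x):
    """Score test of a single-covariate Cox model at beta = 0."""
    U = V = 0.0
    for i in np.flatnonzero(event == 1):
        at = time >= time[i]
        xb = x[at].mean()
        U += x[i] - xb
        V += ((x[at] - xb) ** 2).mean()
    return U ** 2 / V


class TestKaplanMeier:
    def test_hand_product_limit(self):
        out = _outcome([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        curves, _ = kaplan_meier(out, pd.Series(["g"] * 5, index=out["sample_id"]))
        s = dict(zip(curves["g"].times, curves["g"].survival))
        assert s[1.0] == pytest.approx(0.8)
        assert s[2.0] == pytest.approx(0.6)
        assert s[4.0] == pytest.approx(0.3)

    def test_no_events_flat_curve(self):
        out = _outcome([2, 4, 6], [0, 0, 0])
        curves, _ = kaplan_meier(out, pd.Series(["g"] * 3, index=out["sample_id"]))
        assert np.allclose(curves["g"].survival, 1.0)

    def test_record_duplication_invariance(self, rng):
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        single = _outcome(t, e)
        doubled = _outcome(np.r_[t, t], np.r_[e, e])
        c1, _ = kaplan_meier(single, pd.Series(["g"] * 30, index=single["sample_id"]))
        c2, _ = kaplan_meier(doubled, pd.Series(["g"] * 60, index=doubled["sample_id"]))
        assert np.allclose(c1["g"].survival, c2["g"].survival)

    def test_risk_table_counts(self):
        out = _outcome([1, 2, 3, 4], [1, 1, 1, 1])
        _, risk = kaplan_meier(out, pd.Series(["g"] * 4, index=out["sample_id"]),
                               time_grid=np.array([0.0, 2.5]))
        assert risk.loc["g"].tolist() == [4, 2]


class TestLogrank:
    def test_identical_groups_null(self, rng):
        t = rng.exponential(1, 25)
        e = np.ones(25, int)
        out = _outcome(np.r_[t, t], np.r_[e, e])
        g = pd.Series(["a"] * 25 + ["b"] * 25, index=out["sample_id"])
        res = logrank_test(out, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_three_groups(self, rng):
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        gl = rng.choice(["a", "b", "c"], 60)
        out = _outcome(t, e)
        res = logrank_test(out, pd.Series(gl, index=out["sample_id"]))
        assert res.df == 2
        assert res.chi2 == pytest.approx(brute_logrank(t, e, gl), abs=1e-10)

    def test_equals_cox_score_test_two_groups(self, rng):
        t = rng.exponential(1, 80)  # continuous times: no ties
        x = rng.integers(0, 2, 80)
        e = np.ones(80, int)
        out = _outcome(t, e)
        res = logrank_test(out, pd.Series(np.where(x == 1, "b", "a"),
                                          index=out["sample_id"]))
        assert res.chi2 == pytest.approx(cox_score_statistic(t, e, x), abs=1e-8)

    def test_pairwise_reports_bh_alongside(self, rng):
        t = rng.exponential(1, 90)
        e = np.ones(90, int)
        g = pd.Series(np.repeat(["a", "b", "c"], 30))
        t[g.to_numpy() == "c"] *= 3.0
        out = _outcome(t, e)
        res = logrank_test(out, pd.Series(g.to_numpy(), index=out["sample_id"]),
                           pairwise=True)
        assert res.pairwise.shape[0] == 3
        assert (res.pairwise["p_bh"] >= res.pairwise["p"] - 1e-12).all()

    def test_single_group_rejected(self, rng):
        out = _outcome([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="two"):
            logrank_test(out, pd.Series(["g"] * 3, index=out["sample_id"]))


class TestCox:
    def test_parameter_recovery_exponential(self):
        """Mean estimate near the generating log-hazard ratio."""
        est = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 600
            x = rng.standard_normal(n)
            t = rng.exponential(1.0 / np.exp(0.7 * x))
            c = rng.exponential(np.quantile(t, 0.7), n)
            out = pd.DataFrame({"time": np.minimum(t, c),
                                "event": (t <= c).astype(int)})
            fit = fit_cox(pd.DataFrame({"x": x}), out)
            est.append(fit.beta["x"])
        assert abs(np.mean(est) - 0.7) < 0.05

    def test_ci_brackets_hr(self, rng):
        n = 200
        x = rng.standard_normal(n)
        out = pd.DataFrame({"time": rng.exponential(1.0 / np.exp(0.4 * x)),
                            "event": np.ones(n, int)})
        fit = fit_cox(pd.DataFrame({"x": x}), out)
        assert fit.ci95.loc["x", "lo"] < fit.hr["x"] < fit.ci95.loc["x", "hi"]
        assert fit.hr["x"] > 0

    def test_zero_events_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        with pytest.raises(ValueError, match="events"):
            fit_cox(X, out)

    def test_missing_covariates_dropped_with_warning(self, rng):
        n = 50
        x = rng.standard_normal(n)
        x[:3] = np.nan
        out = pd.DataFrame({"time": rng.exponential(1, n), "event": np.ones(n, int)})
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_cox(pd.DataFrame({"x": x}), out)
        assert fit.n == n - 3


class TestSchoenfeld:
    def test_single_covariate_global_equals_marginal(self, rng):
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        out = pd.DataFrame({"time": t, "event": np.ones(n, int)})
        fit = fit_cox(pd.DataFrame({"x": x}), out)
        tab = schoenfeld_test(fit)
        assert tab.loc["x", "p"] == pytest.approx(tab.loc["GLOBAL", "p"], rel=1e-9)

    def test_detects_time_varying_effect(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.standard_normal(n)
            # effect reverses over follow-up: early protective, late harmful
            t = np.where(x > 0, rng.exponential(0.5, n), rng.exponential(1.5, n))
            t2 = np.where(x > 0, rng.exponential(3.0, n), rng.exponential(0.8, n))
            time = np.where(t < 0.4, t, 0.4 + t2)
            out = pd.DataFrame({"time": time, "event": np.ones(n, int)})
            fit = fit_cox(pd.DataFrame({"x": x}), out)
            hits += schoenfeld_test(fit).loc["GLOBAL", "p"] < 0.01
        assert hits >= 7

    def test_too_few_events_rejected(self, rng):
        out = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0]})
        fit_in = pd.DataFrame({"x": [0.5, -0.2, 0.1, 0.9]})
        fit = fit_cox(fit_in, out)
        with pytest.raises(ValueError, match="events"):
            schoenfeld_test(fit)


class TestFactorScreen:
    def test_alpha_zero_selects_nothing(self, small_model, small_cohort):
        dataset, truth = small_cohort
        out = dataset.outcome(truth.config.endpoint).reset_index()
        selected, crude, adjusted = select_survival_factors(
            small_model, out, dataset.clinical, alpha=0.0)
        assert selected == []
        assert adjusted is not None
        assert "age" in adjusted.covariates

    def test_age_adjustment_keeps_factor_hazards_stable(self, small_model,
                                                        small_cohort):
        dataset, truth = small_cohort
        out = dataset.outcome(truth.config.endpoint).reset_index()
        _, crude, adjusted = select_survival_factors(
            small_model, out, dataset.clinical)
        shared = [c for c in crude.covariates if c in adjusted.covariates]
        # age is independent of the factors by construction
        assert np.allclose(crude.beta[shared], adjusted.beta[shared], atol=0.15)


def test_follow_up_truncation_censors_late_events():
    from moclust.survival import truncate_follow_up
    out = pd.DataFrame({"sample_id": list("abc"), "time": [100.0, 180.0, 250.0],
                        "event": [1, 1, 1], "endpoint": "all_cause"})
    trunc = truncate_follow_up(out, 180.0)
    assert trunc["time"].tolist() == [100.0, 180.0, 180.0]
    assert trunc["event"].tolist() == [1, 1, 0]
    with pytest.raises(ValueError):
        truncate_follow_up(out, 0)
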