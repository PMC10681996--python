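"""Endpoints, Kaplan-Meier, Cox regression, cutpoint search, log-rank."""

import numpy as np
import pandas as pd
import pytest

from aspstrat import (
    cox_fit,
    derive_endpoint,
    km_estimate,
    logrank,
    optimal_cutpoint,
    validate_fixed_cutoff,
)
from aspstrat.surv import km_median


def history(**kw):
    row = {
        "patient_id": kw.pop("pid", "P1"),
        "locoregional_months": np.nan,
        "distant_months": np.nan,
        "death_months": np.nan,
        "last_followup_months": 24.0,
    }
    row.update(kw)
    return row


class TestDeriveEndpoint:
    def test_distant_relapse_then_alive(self):
        cohort = pd.DataFrame([history(distant_months=6.0, last_followup_months=30.0)])
        assert derive_endpoint(cohort, "PFS").iloc[0].tolist()[1:] == [6.0, 1]
        assert derive_endpoint(cohort, "FFDM").iloc[0].tolist()[1:] == [6.0, 1]
        assert derive_endpoint(cohort, "LRC").iloc[0].tolist()[1:] == [30.0, 0]
        assert derive_endpoint(cohort, "OS").iloc[0].tolist()[1:] == [30.0, 0]

    def test_event_free_censored_everywhere(self):
        cohort = pd.DataFrame([history(last_followup_months=24.0)])
        for ep in ("PFS", "OS", "LRC", "FFDM"):
            assert derive_endpoint(cohort, ep).iloc[0].tolist()[1:] == [24.0, 0]

    def test_death_without_recurrence(self):
        cohort = pd.DataFrame([history(death_months=12.0, last_followup_months=12.0)])
        assert derive_endpoint(cohort, "PFS").iloc[0].tolist()[1:] == [12.0, 1]
        assert derive_endpoint(cohort, "OS").iloc[0].tolist()[1:] == [12.0, 1]
        # cause-specific convention: death censors LRC / FFDM at death
        assert derive_endpoint(cohort, "LRC").iloc[0].tolist()[1:] == [12.0, 0]
        assert derive_endpoint(cohort, "FFDM").iloc[0].tolist()[1:] == [12.0, 0]

    def test_precomputed_columns_pass_through(self):
        cohort = pd.DataFrame({"patient_id": ["a"], "pfs_time": [7.5], "pfs_event": [1]})
        out = derive_endpoint(cohort, "PFS")
        assert out.iloc[0].tolist() == ["a", 7.5, 1]

    def test_nonpositive_followup_dropped(self):
        cohort = pd.DataFrame(
            [history(pid="bad", last_followup_months=0.0), history(pid="ok")]
        )
        out = derive_endpoint(cohort, "OS")
        assert out["patient_id"].tolist() == ["ok"]

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown endpoint"):
            derive_endpoint(pd.DataFrame([history()]), "TTP")


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        rec = pd.DataFrame({"time": [3.0, 5.0, 9.0], "event": [0, 0, 0]})
        km = km_estimate(rec)
        assert (km["survival"] == 1.0).all()

    def test_single_event_among_four(self):
        rec = pd.DataFrame({"time": [5.0, 8.0, 9.0, 11.0], "event": [1, 0, 0, 0]})
        km = km_estimate(rec)
        assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == pytest.approx(0.75)

    def test_censoring_reduces_risk_set(self):
        # hand product-limit: censor at 2 -> at risk 2 at t=5 -> S = 1 * (1 - 1/2)
        rec = pd.DataFrame({"time": [2.0, 5.0, 7.0], "event": [0, 1, 0]})
        km = km_estimate(rec)
        assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == pytest.approx(0.5)

    def test_tied_events_multiply_simultaneously(self):
        # 5 at risk, 2 events at t=4: S(4) = 1 - 2/5
        rec = pd.DataFrame({"time": [4.0, 4.0, 6.0, 7.0, 9.0], "event": [1, 1, 0, 0, 0]})
        km = km_estimate(rec)
        assert km.loc[km["time"] == 4.0, "survival"].iloc[0] == pytest.approx(0.6)

    def test_matches_lifelines_on_seeded_data(self, survival_fixture):
        from lifelines import KaplanMeierFitter

        rec, _ = survival_fixture
        km = km_estimate(rec)
        kmf = KaplanMeierFitter().fit(rec["time"], rec["event"])
        theirs = kmf.survival_function_at_times(km["time"]).to_numpy()
        assert np.allclose(km["survival"], theirs, atol=1e-12)

    def test_median_survival(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
        assert km_median(rec) == 2.0


class TestCoxFit:
    def test_matches_lifelines_to_1e6_no_ties(self, survival_fixture):
        from lifelines import CoxPHFitter

        rec, marker = survival_fixture
        fit = cox_fit(rec[["time", "event"]], marker)
        df = pd.DataFrame({"T": rec["time"], "E": rec["event"], "x": marker})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert abs(fit.coef[0] - cph.params_.iloc[0]) < 1e-6
        assert abs(fit.se[0] - cph.standard_errors_.iloc[0]) < 1e-6

    def test_multivariate_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 150
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = np.round(rng.exponential(1 / (0.05 * np.exp(0.4 * x1 + 0.6 * x2))), 0) + 1
        c = rng.uniform(5, 40, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})
        X = pd.DataFrame({"x1": x1, "x2": x2})
        fit = cox_fit(rec, X)
        cph = CoxPHFitter().fit(pd.concat([rec.rename(columns={"time": "T", "event": "E"}), X], axis=1), "T", "E")
        assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=5e-6)

    def test_binary_fast_path_equals_general_solver(self, survival_fixture):
        from aspstrat._cox import cox_newton

        rec, marker = survival_fixture
        x = (marker > marker.median()).astype(float)
        fast = cox_fit(rec[["time", "event"]], x)
        general = cox_newton(rec["time"].to_numpy(), rec["event"].to_numpy(), x.to_numpy()[:, None])
        assert fast.coef[0] == pytest.approx(general.coef[0], abs=1e-8)
        assert fast.p[0] == pytest.approx(general.p[0], rel=1e-6)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(15)
        n = 2000
        x = rng.normal(size=n)
        t = rng.exponential(20.0, n)
        c = rng.uniform(5, 60, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})
        fit = cox_fit(rec, x)
        assert 0.93 <= fit.hr[0] <= 1.08

    def test_separation_flagged_not_silent(self):
        # all events in one group: monotone likelihood
        rec = pd.DataFrame(
            {"time": [1, 2, 3, 4, 10, 11, 12, 13], "event": [1, 1, 1, 1, 0, 0, 0, 0]}
        )
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        fit = cox_fit(rec, x)
        assert "separation" in fit.flags

    def test_constant_covariate_rejected(self, survival_fixture):
        rec, _ = survival_fixture
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec[["time", "event"]], np.ones(len(rec)))


class TestOptimalCutpoint:
    def brute_force(self, marker, rec):
        """Independent oracle: scan ALL unique values, restrict to IQR post hoc."""
        vals = np.asarray(marker, dtype=float)
        q1, q3 = np.quantile(vals, [0.25, 0.75], method="median_unbiased")
        best = None
        for c in np.unique(vals):
            if not (q1 <= c <= q3):
                continue
            x = (vals > c).astype(float)
            if x.std() == 0:
                continue
            fit = cox_fit(rec[["time", "event"]], x)
            if not fit.ok:
                continue
            if best is None or fit.p[0] < best[1]:
                best = (float(c), float(fit.p[0]))
        return best

    def test_equals_brute_force_oracle(self, survival_fixture):
        rec, marker = survival_fixture
        res = optimal_cutpoint(marker, rec)
        expected = self.brute_force(marker, rec)
        assert res.cutoff == expected[0]
        assert float(res.fit.p[0]) == pytest.approx(expected[1], rel=1e-9)

    def test_forty_patient_cohort_oracle(self):
        rng = np.random.default_rng(404)
        n = 40
        marker = rng.gamma(3, 6, size=n)
        t = rng.exponential(1 / (0.02 * np.exp(0.04 * marker)))
        c = rng.uniform(10, 60, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})
        res = optimal_cutpoint(marker, rec)
        expected = self.brute_force(marker, rec)
        assert (res.cutoff, float(res.fit.p[0])) == pytest.approx(expected, rel=1e-9)

    def test_cutoff_inside_iqr_and_trace_kept(self, survival_fixture):
        rec, marker = survival_fixture
        res = optimal_cutpoint(marker, rec)
        q1, q3 = res.iqr
        assert q1 <= res.cutoff <= q3
        assert len(res.trace) == res.n_candidates
        assert (res.trace["cutoff"] >= q1).all() and (res.trace["cutoff"] <= q3).all()

    def test_tie_broken_toward_smaller_cutoff(self):
        # marker with only two informative levels inside the IQR gives
        # identical splits -> identical p; smaller candidate must win
        marker = np.array([1.0, 1.0, 2.0, 2.5, 3.0, 3.0, 5.0, 5.0, 6.0, 6.0, 7.0, 7.0])
        rec = pd.DataFrame(
            {
                "time": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13.0],
                "event": [1, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
            }
        )
        res = optimal_cutpoint(marker, rec)
        dup = res.trace[res.trace["p"] == float(res.fit.p[0])]
        assert res.cutoff == dup["cutoff"].min()

    def test_constant_marker_rejected(self, survival_fixture):
        rec, _ = survival_fixture
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(np.ones(len(rec)), rec)

    def test_minimum_requirements(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        with pytest.raises(ValueError, match=">= 10 patients"):
            optimal_cutpoint(np.array([1.0, 2.0, 3.0]), rec)


class TestFixedCutoff:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(55)
        n = 400
        asp = rng.gamma(4, 5, size=n)
        t = rng.exponential(1 / (0.01 * np.exp(np.log(1.06) * asp)))
        c = rng.uniform(10, 80, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})
        val = validate_fixed_cutoff(asp, rec, 19.5)
        assert val["fit"].hr[0] > 1.0
        assert val["logrank_p"] < 0.05
        assert val["n_low"] + val["n_high"] == n

    def test_label_swap_inverts_hazard_ratio(self, survival_fixture):
        rec, marker = survival_fixture
        cut = float(marker.median())
        v1 = validate_fixed_cutoff(marker, rec, cut)
        v2 = validate_fixed_cutoff(-marker, rec, -cut - 1e-9)
        assert v1["fit"].hr[0] == pytest.approx(1.0 / v2["fit"].hr[0], rel=1e-6)

    def test_cutoff_below_minimum_rejected(self, survival_fixture):
        rec, marker = survival_fixture
        with pytest.raises(ValueError, match="empty group"):
            validate_fixed_cutoff(marker, rec, marker.min() - 1.0)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3.0], "event": [1, 0, 1, 1, 0, 1]})
        stat, p = logrank(rec, np.array(["a", "a", "a", "b", "b", "b"]))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_extreme_ordering_tiny_p(self):
        rec = pd.DataFrame(
            {"time": list(range(1, 11)) + list(range(50, 60)), "event": [1] * 10 + [0] * 10}
        )
        groups = np.array(["A"] * 10 + ["B"] * 10)
        stat, p = logrank(rec, groups)
        assert p < 1e-4

    def test_single_group_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError, match=">= 2"):
            logrank(rec, np.array(["a", "a"]))

    def test_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(31)
        rec = pd.DataFrame({"time": rng.exponential(10, 40), "event": np.ones(40, int)})
        ps = []
        for _ in range(200):
            groups = rng.permutation(np.array(["a"] * 20 + ["b"] * 20))
            ps.append(logrank(rec, groups)[1])
        ps = np.array(ps)
        # crude uniformity check: rejection rate near nominal
        assert 0.005 <= (ps < 0.05).mean() <= 0.12
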