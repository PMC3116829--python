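import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromfract import (
    PatientRecord,
    anova_lsd,
    backward_stepwise,
    bootstrap_stability,
    cohort_frame,
    cox_fit,
    km_logrank,
    ward_cutpoint,
)

from .conftest import exponential_cohort


class TestKaplanMeierLogrank:
    def hand_fixture(self):
        # group A: deaths at 1 and 3, censored at 5
        # group B: death at 2, censored at 4, death at 6
        return pd.DataFrame(
            dict(
                time_months=[1, 3, 5, 2, 4, 6],
                event=[True, True, False, True, False, True],
                group=list("AAABBB"),
            )
        )

    def test_hand_computed_product_limit_table(self):
        res = km_logrank(self.hand_fixture(), "group")
        a = res.curves["A"].iloc[:, 0]
        # S_A: drops to 2/3 at t=1, to 1/3 at t=3, flat through censoring
        assert a.loc[1.0] == pytest.approx(2 / 3)
        assert a.loc[3.0] == pytest.approx(1 / 3)
        assert a.loc[5.0] == pytest.approx(1 / 3)
        b = res.curves["B"].iloc[:, 0]
        assert b.loc[2.0] == pytest.approx(2 / 3)
        assert b.loc[6.0] == pytest.approx(0.0)

    def test_hand_computed_logrank_statistic(self):
        # O_A = 2, E_A = 3/6 + 2/5 + 2/4 = 1.4, V = 0.25 + 0.24 + 0.25
        # chi² = (2 − 1.4)² / 0.74 = 18/37
        res = km_logrank(self.hand_fixture(), "group")
        assert res.statistic == pytest.approx(18 / 37, abs=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(18 / 37, 1), abs=1e-12)

    def test_identical_groups_have_zero_statistic(self):
        df = self.hand_fixture()
        df["group"] = "A"
        dup = pd.concat([df, df.assign(group="B")], ignore_index=True)
        res = km_logrank(dup, "group")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_flagged(self):
        df = self.hand_fixture()
        df["event"] = False
        res = km_logrank(df, "group")
        assert res.no_events
        assert math.isnan(res.p_value)
        for curve in res.curves.values():
            assert (curve.iloc[:, 0] == 1.0).all()

    def test_single_group_rejected(self):
        df = self.hand_fixture()
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(df, np.repeat("A", len(df)))


class TestCoxFit:
    def test_closed_form_single_binary_covariate(self):
        # times 1,2,3,4; events 1,1,0,1; x 1,0,1,0 — the score equation
        # reduces to u² = 2 with u = exp(B), so B = ln(2)/2
        df = pd.DataFrame(
            dict(time_months=[1.0, 2.0, 3.0, 4.0],
                 event=[True, True, False, True],
                 x=[1.0, 0.0, 1.0, 0.0])
        )
        fit = cox_fit(df, ["x"])
        assert fit.coefficients["x"] == pytest.approx(math.log(2) / 2, abs=1e-6)

    def test_grid_oracle_on_random_data(self):
        # golden-section maximization of the hand-coded partial likelihood
        df = exponential_cohort(60, 0.7, seed=42)
        t = df["time_months"].to_numpy()
        e = df["event"].to_numpy()
        x = df["x"].to_numpy()

        def loglik(b):
            order = np.argsort(t)
            ts, es, xs = t[order], e[order], x[order]
            ll = 0.0
            for i in range(len(ts)):
                if es[i]:
                    risk = xs[i:]  # all times distinct
                    ll += b * xs[i] - np.log(np.sum(np.exp(b * risk)))
            return ll

        lo, hi = -5.0, 5.0
        phi = (math.sqrt(5) - 1) / 2
        for _ in range(80):
            m1 = hi - phi * (hi - lo)
            m2 = lo + phi * (hi - lo)
            if loglik(m1) < loglik(m2):
                lo = m1
            else:
                hi = m2
        b_oracle = (lo + hi) / 2
        fit = cox_fit(df, ["x"])
        assert fit.coefficients["x"] == pytest.approx(b_oracle, abs=1e-6)

    def test_scaling_reparameterization_invariance(self):
        df = exponential_cohort(120, 0.8, seed=7)
        b1 = cox_fit(df, ["x"]).coefficients["x"]
        for c in (100.0, 0.01):
            scaled = df.assign(x=df["x"] / c)
            b2 = cox_fit(scaled, ["x"]).coefficients["x"]
            assert abs(b2 / c - b1) < 1e-8

    def test_single_stratum_equals_unstratified(self):
        df = exponential_cohort(80, 0.5, seed=9)
        df["grp"] = "only"
        plain = cox_fit(df, ["x"])
        strat = cox_fit(df, ["x"], strata="grp")
        assert strat.coefficients["x"] == pytest.approx(
            plain.coefficients["x"], abs=1e-8
        )

    def test_adverse_covariate_gets_positive_coefficient(self):
        df = exponential_cohort(200, 1.0, seed=3)
        fit = cox_fit(df, ["x"])
        assert fit.coefficients["x"] > 0
        protective = exponential_cohort(200, -1.0, seed=4)
        assert cox_fit(protective, ["x"]).coefficients["x"] < 0

    def test_iss_expands_with_stage_three_reference(self):
        rng = np.random.default_rng(15)
        records = []
        for i in range(90):
            stage = ["I", "II", "III"][i % 3]
            lp = {"I": -2.0, "II": -1.0, "III": 0.0}[stage]
            t = rng.exponential(1.0 / (0.05 * math.exp(lp)))
            records.append(
                PatientRecord(case_id=f"c{i}", time_months=max(t, 1e-3),
                              event=True, iss_stage=stage)
            )
        fit = cox_fit(records, ["iss_stage"])
        assert set(fit.coefficients) == {"iss_I", "iss_II"}
        assert fit.coefficients["iss_I"] < fit.coefficients["iss_II"] < 0

    def test_null_p_values_are_uniform(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            x = rng.normal(0, 1, 150)
            t = rng.exponential(1 / 0.05, 150)
            df = pd.DataFrame(
                dict(time_months=t, event=np.ones(150, bool), x=x)
            )
            ps.append(cox_fit(df, ["x"]).p_values["x"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self):
        df = exponential_cohort(30, 0.5, seed=1)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["flat"])

    def test_no_events_rejected(self):
        df = exponential_cohort(30, 0.5, seed=1)
        df["event"] = False
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])


class TestBackwardStepwise:
    def test_single_significant_candidate_retained(self):
        df = exponential_cohort(150, 1.2, seed=20)
        model = backward_stepwise(df, ["x"])
        assert model.included == frozenset({"x"})

    def test_strong_kept_noise_dropped(self):
        df = exponential_cohort(300, 2.0, seed=21, binary=True,
                                extra_noise=True)
        model = backward_stepwise(df, ["x", "noise"])
        assert model.included == frozenset({"x"})

    def test_pure_noise_usually_gives_empty_model(self):
        empties = 0
        for s in range(12):
            df = exponential_cohort(200, 0.0, seed=50 + s, extra_noise=True)
            model = backward_stepwise(df, ["x", "noise"])
            empties += model.is_empty
        assert empties >= 8  # ~81% expected at the 0.10 removal threshold

    def test_no_candidates_rejected(self):
        df = exponential_cohort(30, 0.5, seed=2)
        with pytest.raises(ValueError):
            backward_stepwise(df, [])


class TestBootstrapStability:
    def test_same_seed_reproduces_exactly(self):
        df = exponential_cohort(100, 1.5, seed=30, binary=True,
                                extra_noise=True)
        a = bootstrap_stability(df, ["x", "noise"], n_boot=10, seed=99)
        b = bootstrap_stability(df, ["x", "noise"], n_boot=10, seed=99)
        assert a.inclusion_freq == b.inclusion_freq
        assert a.n_retries == b.n_retries

    def test_single_resample_matches_direct_stepwise(self):
        df = exponential_cohort(120, 1.5, seed=31, binary=True,
                                extra_noise=True)
        res = bootstrap_stability(df, ["x", "noise"], n_boot=1, seed=5)
        # reconstruct the resample the generator drew
        rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
        idx = rng.integers(0, len(df), len(df))
        direct = backward_stepwise(df.iloc[idx].reset_index(drop=True),
                                   ["x", "noise"])
        for term in ("x", "noise"):
            assert res.inclusion_freq[term] == float(term in direct.included)

    def test_strong_beats_null_and_null_can_be_absent(self):
        df = exponential_cohort(150, 2.0, seed=32, binary=True,
                                extra_noise=True)
        res = bootstrap_stability(df, ["x", "noise"], n_boot=20, seed=6)
        assert res.inclusion_freq["x"] > res.inclusion_freq["noise"]
        assert 0.0 <= res.inclusion_freq["noise"] <= 1.0


def brute_two_partition(values):
    """Exhaustive contiguous 2-partition minimizing within-cluster SS."""
    v = np.sort(np.asarray(values, float))
    best = None
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        ss = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if best is None or ss < best[0] - 1e-12:
            best = (ss, (v[i - 1] + v[i]) / 2)
    return best[1]


class TestWardCutpoint:
    def test_symmetric_clusters_cut_in_middle(self):
        assert ward_cutpoint([1, 1, 1, 9, 9, 9]) == pytest.approx(5.0)

    def test_fd_like_example(self):
        assert ward_cutpoint([2.07, 2.09, 2.10, 2.20, 2.22]) == pytest.approx(2.15)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            ward_cutpoint([2.0, 2.0, 2.0])

    def test_matches_exhaustive_search_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            v = np.round(rng.normal(0, 1, n), 3)
            if np.unique(v).size < 2:
                continue
            assert ward_cutpoint(v) == pytest.approx(brute_two_partition(v))

    def test_agrees_with_scipy_ward_on_separated_data(self):
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(2.10, 0.01, 25),
                            rng.normal(2.20, 0.01, 25)])
        cut = ward_cutpoint(v)
        z = linkage(v.reshape(-1, 1), method="ward")
        labels = fcluster(z, t=2, criterion="maxclust")
        lo = v[labels == labels[np.argmin(v)]].max()
        hi = v[labels != labels[np.argmin(v)]].min()
        assert cut == pytest.approx((lo + hi) / 2)

    def test_bimodal_cutpoint_lands_between_modes(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(2.10, 0.02, 30),
                                rng.normal(2.18, 0.02, 30)])
            hits += 2.10 < ward_cutpoint(v) < 2.18
        assert hits >= 38


class TestAnovaLSD:
    def test_hand_computed_three_group_fixture(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB = 42, MSW = 1, F = 21
        groups = {"x": [1, 2, 3], "y": [2, 3, 4], "z": [6, 7, 8]}
        res = anova_lsd(groups)
        assert res.f_statistic == pytest.approx(21.0, abs=1e-9)
        assert res.p_value == pytest.approx(stats.f.sf(21.0, 2, 6), abs=1e-12)
        assert bool(res.significant.loc["x", "z"])
        assert bool(res.significant.loc["y", "z"])
        assert not bool(res.significant.loc["x", "y"])
        # LSD t for x vs z: -5 / sqrt(1·(1/3+1/3)) = -6.1237
        assert res.pairwise_p.loc["x", "z"] == pytest.approx(
            2 * stats.t.sf(5 / math.sqrt(2 / 3), 6), abs=1e-12
        )

    def test_identical_groups_not_significant(self):
        g = list(np.random.default_rng(0).normal(0, 1, 20))
        res = anova_lsd({"a": g, "b": g})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant.to_numpy().any()

    def test_single_shifted_group_drives_all_its_pairs(self):
        rng = np.random.default_rng(4)
        groups = {k: list(rng.normal(0, 1, 25)) for k in "abc"}
        groups["d"] = list(rng.normal(5, 1, 25))  # 5 pooled SDs away
        res = anova_lsd(groups)
        for a in "abc":
            assert bool(res.significant.loc[a, "d"])
        assert res.p_value < 1e-6

    def test_zero_variance_flagged(self):
        res = anova_lsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.degenerate

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0], "b": [1.0, 2.0]})


class TestPatientRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            PatientRecord(case_id="x", time_months=0.0, event=True)
        with pytest.raises(ValueError):
            PatientRecord(case_id="x", time_months=1.0, event=True,
                          iss_stage="IV")

    def test_cohort_frame_roundtrip(self):
        rec = PatientRecord(case_id="a", time_months=12.0, event=True,
                            iss_stage="II", covariates={"mean_fd": 2.1})
        df = cohort_frame([rec])
        assert df.loc[0, "mean_fd"] == 2.1
        assert df.loc[0, "iss_stage"] == "II"
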