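"""Longitudinal statistics: NOL index, outlier screening, mixed-effects
trajectory fits (cross-checked against statsmodels MixedLM), the
90%-change RCA rule, BH correction and the age of significance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vasculong import stats as st
from vasculong.synthetic import (CohortSpec, TrajectorySpec, simulate_cohort,
                                 simulate_nol)


class TestNolIndex:
    @pytest.mark.parametrize("t_nw,t_se,expected", [
        (150.0, 150.0, 0.5),
        (0.0, 100.0, 1.0),
        (10.0, 30.0, 0.75),
    ])
    def test_worked_examples(self, t_nw, t_se, expected):
        assert st.nol_index(t_nw, t_se) == pytest.approx(expected)

    def test_boundary_flags_decline(self):
        assert st.nol_decline(st.nol_index(150.0, 150.0))
        assert not st.nol_decline(0.51)

    def test_zero_total_time_undefined(self):
        with pytest.raises(ValueError):
            st.nol_index(0.0, 0.0)

    def test_round_trip_through_generator(self):
        tab = simulate_nol(3, (11, 15), 0.75, seed=1)
        z = st.nol_table_to_index(tab)["z"]
        assert np.allclose(z, 0.75)


class TestExcludeOutliers:
    def _table(self, values, group="AD"):
        ages = np.tile([11, 15, 19, 23, 27, 31, 35], len(values) // 7)
        return pd.DataFrame({
            "animal_id": np.repeat([f"A{i}" for i in range(len(values) // 7)],
                                   7),
            "group": group, "age_weeks": ages, "property": "p",
            "value": values})

    def test_gross_outlier_is_the_removed_row(self):
        vals = list(2.0 - 0.01 * np.tile(np.arange(7), 3))
        vals[10] = 50.0                     # one corrupted measurement
        tab = self._table(np.array(vals))
        kept, removed = st.exclude_outliers(tab, "p")
        assert len(removed) == 1
        assert removed.iloc[0]["value"] == 50.0

    def test_noiseless_data_removes_nothing(self):
        vals = 2.0 - 0.01 * np.tile(np.arange(7), 3)
        kept, removed = st.exclude_outliers(self._table(vals), "p")
        assert len(removed) == 0
        assert kept.equals(self._table(vals))

    def test_constant_data_removes_nothing(self):
        kept, removed = st.exclude_outliers(self._table(np.ones(21)), "p")
        assert len(removed) == 0


class TestFitTrajectory:
    def test_noiseless_linear_recovered_exactly(self):
        spec = CohortSpec(trajectories={"p": {
            "AD": TrajectorySpec(shape="linear", intercept=10.0,
                                 slope_pct_month=-13.0),
            "WT": TrajectorySpec(shape="linear", intercept=10.0,
                                 slope_pct_month=-7.0)}}, seed=0)
        fit = st.fit_trajectory(simulate_cohort(spec), "p", "linear")
        assert st.rate_of_change(fit, "AD")[0] == pytest.approx(-13.0,
                                                                abs=1e-6)
        assert st.rate_of_change(fit, "WT")[0] == pytest.approx(-7.0,
                                                                abs=1e-6)
        # variance components collapse on noiseless data
        assert fit.fit.sig2 < 1e-6

    def test_linear_fit_matches_mixedlm_single_group(self):
        spec = CohortSpec(trajectories={"p": {
            g: TrajectorySpec(shape="linear", intercept=1.0,
                              slope_pct_month=-5.0, re_intercept_sd=0.05,
                              residual_sd=0.05) for g in ("AD", "WT")}},
            seed=7)
        tab = simulate_cohort(spec)
        sub = tab[tab.group == "AD"]
        mine = st.MixedFit("linear").fit(sub)
        x = sm.add_constant((sub.age_weeks - 11).to_numpy())
        ref = sm.MixedLM(sub.value.to_numpy(), x,
                         groups=sub.animal_id.to_numpy()).fit(reml=False)
        assert np.allclose(mine.betas["AD"], np.asarray(ref.params)[:2],
                           atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(mine.cov["AD"])),
                           np.asarray(ref.bse)[:2], rtol=1e-3)
        assert -mine.nll == pytest.approx(ref.llf, abs=1e-3)

    def test_animal_relabeling_within_group_is_irrelevant(self):
        spec = CohortSpec(trajectories={"p": {
            g: TrajectorySpec(shape="linear", intercept=1.0,
                              slope_pct_month=-5.0, re_intercept_sd=0.05,
                              residual_sd=0.03) for g in ("AD", "WT")}},
            seed=3)
        tab = simulate_cohort(spec)
        a = st.fit_trajectory(tab, "p", "linear")
        relabeled = tab.copy()
        mapping = {f"AD{i:02d}": f"AD{((i + 2) % 7) + 1:02d}"
                   for i in range(1, 8)}
        relabeled["animal_id"] = relabeled["animal_id"].replace(mapping)
        b = st.fit_trajectory(relabeled, "p", "linear")
        for g in ("AD", "WT"):
            assert np.allclose(a.fit.betas[g], b.fit.betas[g], atol=1e-5)

    def test_insufficient_data_rejected(self):
        df = pd.DataFrame({"animal_id": ["A", "B"], "group": ["AD", "WT"],
                           "age_weeks": [11, 11], "property": "p",
                           "value": [1.0, 1.0]})
        with pytest.raises(ValueError):
            st.fit_trajectory(df, "p", "linear")


class TestSelectModel:
    def test_tie_goes_to_linear(self):
        class Dummy:
            def __init__(self, aicc):
                self.aicc = aicc
                self.model_kind = "x"
        lin, sig = Dummy(5.0), Dummy(5.0)
        lin.model_kind, sig.model_kind = "linear", "sigmoid"
        assert st.select_model(lin, sig) is lin
        sig.aicc = 4.0
        assert st.select_model(lin, sig) is sig


def _manual_fit(kind, betas, cov):
    """A TrajectoryFit with prescribed parameters (no fitting) for testing
    the downstream rules in isolation."""
    m = st.MixedFit(kind)
    m.groups = tuple(sorted(betas))
    m.betas = {g: np.asarray(b, dtype=float) for g, b in betas.items()}
    m.cov = {g: np.asarray(c, dtype=float) for g, c in cov.items()}
    m.n_animals = {g: 7 for g in m.groups}
    return st.TrajectoryFit(model_kind=kind, fit=m)


class TestRateOfChange:
    def test_linear_slope_conversion(self):
        fit = _manual_fit("linear", {"AD": [1.0, -0.0325]},
                          {"AD": np.zeros((2, 2))})
        rca, _ = st.rate_of_change(fit, "AD")
        assert rca == pytest.approx(-13.0)

    def test_flat_sigmoid_is_zero(self):
        fit = _manual_fit("sigmoid", {"AD": [1.0, 0.0, 2.0, 23.0]},
                          {"AD": np.zeros((4, 4))})
        assert st.rate_of_change(fit, "AD")[0] == pytest.approx(0.0)

    def test_sigmoid_matches_dense_grid_oracle(self):
        c, L, k, b = 1.0, -0.2, 2.0, 23.0
        fit = _manual_fit("sigmoid", {"AD": [c, L, k, b]},
                          {"AD": np.zeros((4, 4))})
        rca, _ = st.rate_of_change(fit, "AD")
        # independent dense-grid evaluation of the stated rule
        ages = np.arange(11.0, 35.0 + 1e-9, 0.0001)
        y = c + L / (1 + np.exp(k * (b - ages)))
        rng_ = y.max() - y.min()
        y5, y95 = y.min() + 0.05 * rng_, y.min() + 0.95 * rng_
        t5 = ages[np.argmax(y <= y95)]        # decreasing curve
        t95 = ages[np.argmax(y <= y5)]
        oracle = -0.9 * rng_ / (t95 - t5) * 4.0 * 100.0
        assert rca == pytest.approx(oracle, abs=1e-4 * abs(oracle) + 1e-6)


class TestCompareGroups:
    def test_single_group_errors(self):
        fit = _manual_fit("linear", {"AD": [1.0, 0.0]},
                          {"AD": np.eye(2)})
        with pytest.raises(ValueError):
            st.compare_groups(fit)

    def test_identical_groups_p_near_one(self):
        fit = _manual_fit("linear",
                          {"AD": [1.0, -0.01], "WT": [1.0, -0.01]},
                          {"AD": 1e-4 * np.eye(2), "WT": 1e-4 * np.eye(2)})
        assert st.compare_groups(fit) == pytest.approx(1.0)


class TestCompareGroupsPower:
    def test_study_scale_effect_detected_in_majority_of_replicates(self):
        """AD −13 vs WT −7 %/month, 7 vs 6 animals, moderate noise: the
        slope-interaction test fires at alpha=0.05 in most replicates."""
        hits, n_rep = 0, 20
        for r in range(n_rep):
            spec = CohortSpec(trajectories={"p": {
                "AD": TrajectorySpec(shape="linear", intercept=1.0,
                                     slope_pct_month=-13.0,
                                     re_intercept_sd=0.05, re_slope_sd=1.5,
                                     residual_sd=0.05),
                "WT": TrajectorySpec(shape="linear", intercept=1.0,
                                     slope_pct_month=-7.0,
                                     re_intercept_sd=0.05, re_slope_sd=1.5,
                                     residual_sd=0.05)}}, seed=600_000 + r)
            fit = st.fit_trajectory(simulate_cohort(spec), "p", "linear")
            hits += st.compare_groups(fit) < 0.05
        assert hits / n_rep > 0.5


class TestLaggedCorrelationNull:
    def test_false_positive_rate_near_alpha(self):
        """Independent property and NOL series: the slope test fires at
        roughly its nominal 5% rate."""
        rng = np.random.default_rng(0)
        ages = np.array([11, 15, 19, 23, 27, 31, 35], float)
        hits = total = 0
        for rep in range(100):
            rows, nol_rows = [], []
            for a in range(7):
                vals = 1.0 + rng.normal(0, 0.05, len(ages)).cumsum() * 0.2
                z = np.clip(0.6 + rng.normal(0, 0.08, len(ages)), 0.05, 0.95)
                for age, v, zz in zip(ages, vals, z):
                    rows.append((f"AD{a:02d}", "AD", age, "p", v))
                    nol_rows.append((f"AD{a:02d}", "AD", age,
                                     (1 - zz) * 300, zz * 300))
            cohort = pd.DataFrame(rows, columns=["animal_id", "group",
                                                 "age_weeks", "property",
                                                 "value"])
            nol = pd.DataFrame(nol_rows, columns=["animal_id", "group",
                                                  "age_weeks", "t_nw_s",
                                                  "t_se_s"])
            out = st.lagged_correlation(cohort, nol, lags=(0,))
            if len(out):
                total += 1
                hits += bool(out.iloc[0].significant)
        assert total >= 90
        assert hits / total <= 0.12


def _bh_oracle(p, alpha=0.05):
    """Textbook step-up: find the largest i with p_(i) <= i/m * alpha."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    flags = np.zeros(m, bool)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i / m * alpha:
            k = i
    flags[order[:k]] = True
    return flags


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # m=25: thresholds i/25*0.05 start at 0.002, so p=0.01 fails and
        # the step-up rejects nothing
        p = [0.01, 0.02, 0.03] + [0.9] * 22
        _, flags = st.bh_adjust(p)
        assert list(flags) == list(_bh_oracle(p))
        assert not flags.any()
        # with a genuinely small leading p the first three are recovered
        p2 = [1e-4, 2e-4, 3e-4] + [0.9] * 22
        _, flags2 = st.bh_adjust(p2)
        assert list(flags2) == list(_bh_oracle(p2))
        assert flags2[:3].all() and not flags2[3:].any()

    def test_all_ones_none_significant(self):
        _, flags = st.bh_adjust([1.0] * 10)
        assert not flags.any()

    def test_single_p_unchanged(self):
        adj, flags = st.bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, 25) ** 2
            _, flags = st.bh_adjust(p)
            assert np.array_equal(flags, _bh_oracle(p))

    def test_flags_monotone_in_raw_p(self, rng):
        p = np.sort(rng.uniform(0, 0.4, 25))
        _, flags = st.bh_adjust(p)
        # once a larger p is significant, all smaller ones are too
        assert np.all(np.diff(flags.astype(int)) <= 0)


class TestAgeOfSignificance:
    def test_identical_fits_never_separate(self):
        cov = {g: 1e-4 * np.eye(2) for g in ("AD", "WT")}
        fit = _manual_fit("linear", {"AD": [1.0, -0.02],
                                     "WT": [1.0, -0.02]}, cov)
        assert st.age_of_significance(fit) is None

    def test_linear_crossing_matches_analytic_solution(self):
        # bands: mu_g(t) ± z*sqrt(var_int + var_slope*(t-11)^2), no covar
        b_ad, b_wt = [1.0, -0.03], [1.0, 0.0]
        v = np.diag([1e-4, 1e-6])
        fit = _manual_fit("linear", {"AD": b_ad, "WT": b_wt},
                          {"AD": v, "WT": v})
        z = float(__import__("scipy.stats", fromlist=["norm"]
                             ).norm.ppf(0.5 + 0.93 / 2))

        def dist(t):
            dt = t - 11.0
            half = z * np.sqrt(v[0, 0] + v[1, 1] * dt ** 2)
            return (b_wt[0] + b_wt[1] * dt - half) - (
                b_ad[0] + b_ad[1] * dt + half)

        from scipy.optimize import brentq
        analytic = brentq(dist, 11.01, 34.99)
        aos = st.age_of_significance(fit)
        assert aos == pytest.approx(analytic, abs=0.1 + 1e-9)

    def test_symmetric_in_group_order(self):
        v = np.diag([1e-4, 1e-6])
        fit = _manual_fit("linear", {"AD": [1.0, -0.03], "WT": [1.0, 0.0]},
                          {"AD": v, "WT": v})
        assert st.age_of_significance(fit, "AD", "WT") == \
            st.age_of_significance(fit, "WT", "AD")


class TestLaggedCorrelation:
    def _cohort_and_nol(self, lag=0, seed=0):
        rng = np.random.default_rng(seed)
        ages = np.array([11, 15, 19, 23, 27, 31, 35], float)
        rows, nol_rows = [], []
        for a in range(6):
            traj = 1.0 - 0.02 * (ages - 11) + rng.normal(0, 0.01, len(ages))
            for age, v in zip(ages, traj):
                rows.append((f"AD{a:02d}", "AD", age, "p", v))
            # NOL tracks the property with the requested delay
            for age, v in zip(ages + lag, traj):
                z = np.clip(0.2 + 0.6 * v + rng.normal(0, 0.005), 0.01, 0.99)
                nol_rows.append((f"AD{a:02d}", "AD", age,
                                 (1 - z) * 300, z * 300))
        cohort = pd.DataFrame(rows, columns=["animal_id", "group",
                                             "age_weeks", "property",
                                             "value"])
        nol = pd.DataFrame(nol_rows, columns=["animal_id", "group",
                                              "age_weeks", "t_nw_s",
                                              "t_se_s"])
        return cohort, nol

    def test_perfect_dependence_at_lag_zero(self):
        cohort, nol = self._cohort_and_nol(lag=0)
        out = st.lagged_correlation(cohort, nol, lags=(0,))
        row = out[(out.property == "p") & (out.lag_weeks == 0)].iloc[0]
        assert row.p < 1e-6
        assert row.sign == 1

    def test_lag_recovery(self):
        cohort, nol = self._cohort_and_nol(lag=4, seed=1)
        out = st.lagged_correlation(cohort, nol, lags=(0, 4, 8, 12))
        assert out["max_corr_lag"].iloc[0] == 4

    def test_too_few_overlapping_ages_skipped(self):
        cohort, nol = self._cohort_and_nol(lag=0)
        nol2 = nol[nol.age_weeks <= 15]
        out = st.lagged_correlation(cohort, nol2, lags=(8,))
        assert len(out) == 0


class TestPanel:
    def test_deterministic_rerun(self):
        spec = CohortSpec(trajectories={
            "a": {"AD": TrajectorySpec(shape="linear", intercept=1.0,
                                       slope_pct_month=-5.0,
                                       re_intercept_sd=0.05,
                                       residual_sd=0.03),
                  "WT": TrajectorySpec(shape="linear", intercept=1.0,
                                       slope_pct_month=0.0,
                                       re_intercept_sd=0.05,
                                       residual_sd=0.03)}}, seed=4)
        tab = simulate_cohort(spec)
        f1 = st.panel_to_frame(st.run_property_panel(tab))
        f2 = st.panel_to_frame(st.run_property_panel(tab))
        pd.testing.assert_frame_equal(f1, f2)

    def test_failures_are_isolated(self):
        spec = CohortSpec(trajectories={"good": {
            g: TrajectorySpec(shape="linear", intercept=1.0,
                              slope_pct_month=-3.0, residual_sd=0.02)
            for g in ("AD", "WT")}}, seed=0)
        tab = simulate_cohort(spec)
        broken = pd.DataFrame({"animal_id": ["A1"], "group": ["AD"],
                               "age_weeks": [11.0], "property": ["bad"],
                               "value": [1.0]})
        results = st.run_property_panel(pd.concat([tab, broken]))
        by_name = {r.property_name: r for r in results}
        assert by_name["bad"].error is not None
        assert by_name["good"].error is None
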