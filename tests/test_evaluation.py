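"""Kaplan-Meier, log-rank and the risk-group report tables."""

import numpy as np
import pandas as pd
import pytest

import prognosig as pg
from prognosig.evaluation import (
    kaplan_meier,
    logrank_chi2,
    logrank_test,
    multivariate_report,
    risk_group_table,
    truncate_follow_up,
)


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = kaplan_meier([5.0, 10.0, 15.0], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_three_subject_hand_example(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.survival_at(2.5) == pytest.approx(1 / 3)
        assert km.survival_at(0.5) == 1.0

    def test_tracks_exponential_closed_form(self):
        """Uncensored exponential draws: sup |S-hat - exp(-lambda t)|
        stays under the 99% KS band at n=100, over repeated seeds."""
        lam = 0.05
        bound = 1.63 / np.sqrt(100)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.exponential(1 / lam, 100)
            km = kaplan_meier(t, np.ones(100, int))
            sup = np.max(
                np.abs(km.survival - np.exp(-lam * km.event_times))
            )
            assert sup < bound

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(20, 50)
        e = rng.binomial(1, 0.7, 50)
        a = kaplan_meier(t, e)
        b = kaplan_meier(t * 30.44, e)  # months -> days
        np.testing.assert_allclose(a.survival, b.survival)

    def test_horizon_truncation(self):
        t, e = truncate_follow_up([10.0, 70.0, 80.0], [1, 1, 0], 60.0)
        assert list(t) == [10.0, 60.0, 60.0]
        assert list(e) == [1, 0, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = np.array([2.0, 4.0, 6.0, 8.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_doubling_the_cohort_sharpens_p(self):
        rng = np.random.default_rng(9)
        t = np.concatenate(
            [rng.exponential(10, 20), rng.exponential(25, 20)]
        )
        e = np.ones(40, int)
        g = np.array(["a"] * 20 + ["b"] * 20)
        single = logrank_test(t, e, g)
        double = logrank_test(
            np.concatenate([t, t]), np.concatenate([e, e]),
            np.concatenate([g, g]),
        )
        assert double.chi_square > single.chi_square
        assert double.p_value < single.p_value

    def test_fast_statistic_matches_lifelines(self):
        rng = np.random.default_rng(4)
        t = np.round(rng.exponential(12, 60), 0) + 1  # ties
        e = rng.binomial(1, 0.7, 60)
        g = rng.binomial(1, 0.5, 60).astype(bool)
        e[0] = 1
        ours = logrank_chi2(t, e, g)
        ref = logrank_test(t, e, np.where(g, "x", "y")).chi_square
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_toy_p_matches_permutation_null(self):
        """8-subject toy: the asymptotic log-rank p agrees with a
        50,000-draw permutation null of the group labels."""
        times = np.arange(1, 9, dtype=float)
        events = np.array([0, 1, 1, 1, 0, 1, 0, 0])
        mask = np.zeros(8, bool)
        mask[[1, 4, 6, 7]] = True
        obs = logrank_chi2(times, events, mask)
        p_asym = logrank_test(
            times, events, np.where(mask, "b", "a")
        ).p_value
        rng = np.random.default_rng(123)
        hits = 0
        n_perm = 50_000
        for _ in range(n_perm):
            hits += logrank_chi2(
                times, events, rng.permutation(mask)
            ) >= obs - 1e-12
        p_perm = hits / n_perm
        # MC s.d. ~ 0.0017 at p ~ 0.17; allow 3 s.d. plus the tiny
        # chi-square approximation gap of this instance
        assert abs(p_asym - p_perm) < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_hr_orientation_follows_levels(self):
        rng = np.random.default_rng(11)
        t = np.concatenate([rng.exponential(8, 30), rng.exponential(30, 30)])
        e = np.ones(60, int)
        g = np.array(["high"] * 30 + ["low"] * 30)
        hr_high = logrank_test(t, e, g, levels=("low", "high")).hazard_ratio
        hr_low = logrank_test(t, e, g, levels=("high", "low")).hazard_ratio
        assert hr_high == pytest.approx(1 / hr_low, rel=1e-9)
        assert hr_high > 1


def _preds_from(clinical, groups):
    return [
        pg.RiskPrediction(
            sample_id=s, prognostic_index=0.0, ci95=(0, 0), risk_group=g
        )
        for s, g in zip(clinical.sample_ids, groups)
    ]


class TestRiskGroupTable:
    @pytest.fixture()
    def cohort(self):
        _, clinical, truth = pg.generate_cohort(
            pg.SimulationConfig(n_samples=120, n_probes=20, n_informative=0,
                                seed=31)
        )
        return clinical, truth

    def test_zero_event_group_has_full_survival(self, cohort):
        clinical, _ = cohort
        # call every censored sample low risk and drop their events
        groups = np.where(clinical.events == 1, "high", "low")
        table = risk_group_table(
            _preds_from(clinical, groups), clinical, strata=None
        )
        low = table[table["risk_group"] == "low"].iloc[0]
        assert low["survival_60m_pct"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_within_series(self, cohort):
        clinical, truth = cohort
        groups = truth.true_risk_half.loc[clinical.sample_ids]
        table = risk_group_table(
            _preds_from(clinical, groups), clinical, strata="stage"
        )
        assert table["percent_of_series"].sum() == pytest.approx(100.0)

    def test_stratified_rows_match_direct_subsets(self, cohort):
        clinical, truth = cohort
        groups = truth.true_risk_half.loc[clinical.sample_ids]
        table = risk_group_table(
            _preds_from(clinical, groups), clinical, strata="stage"
        )
        for stage in (2, 3):
            ids = clinical.data.index[clinical.data["stage"] == stage]
            sub_clin = clinical.subset(ids.tolist())
            sub_table = risk_group_table(
                _preds_from(sub_clin, groups.loc[ids]), sub_clin, strata=None
            )
            for _, row in sub_table.iterrows():
                match = table[
                    (table["stage"] == stage)
                    & (table["risk_group"] == row["risk_group"])
                ].iloc[0]
                assert match["survival_60m_pct"] == pytest.approx(
                    row["survival_60m_pct"]
                )
                assert match["n"] == row["n"]

    def test_single_group_stratum_p_not_computable(self, cohort):
        clinical, _ = cohort
        table = risk_group_table(
            _preds_from(clinical, ["high"] * clinical.n_samples),
            clinical,
            strata=None,
        )
        assert np.isnan(table["logrank_p"]).all()


class TestMultivariateReport:
    @pytest.fixture()
    def cohort(self):
        _, clinical, truth = pg.generate_cohort(
            pg.SimulationConfig(n_samples=150, n_probes=20, n_informative=0,
                                seed=17)
        )
        return clinical, truth

    def test_random_risk_group_hr_ci_covers_one(self, cohort):
        """Null coverage: with risk groups assigned at random the HR CI
        for the group covers 1.0 in >= 90% of 50 seeded repetitions."""
        clinical, _ = cohort
        covered = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            groups = np.where(
                rng.random(clinical.n_samples) < 0.5, "high", "low"
            )
            summary, _ = multivariate_report(
                clinical, _preds_from(clinical, groups)
            )
            lo = summary.loc["risk_group_high", "hr_ci_low"]
            hi = summary.loc["risk_group_high", "hr_ci_high"]
            covered += lo <= 1.0 <= hi
        assert covered >= 45

    def test_planted_risk_effect_recovered(self):
        """Risk-group log-hazard 1.2 with a confounding stage effect:
        the adjusted HR estimate stays within the simulation CI."""
        rng = np.random.default_rng(55)
        n = 400
        stage = rng.choice([2, 3], n, p=[0.5, 0.5])
        high = (rng.random(n) < 0.35 + 0.3 * (stage == 3)).astype(int)
        age = rng.normal(65, 10, n)
        lam = 0.01 * np.exp(1.2 * high + 0.5 * (stage - 2.5))
        T = rng.exponential(1 / lam)
        C = rng.exponential(60, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        clinical = pg.ClinicalTable(
            pd.DataFrame(
                {
                    "age_years": age,
                    "gender": "unknown",
                    "grade": rng.choice([1, 2, 3], n),
                    "stage": stage,
                    "time_months": t,
                    "event": e,
                },
                index=pd.Index([f"s{i}" for i in range(n)],
                               name="sample_id"),
            )
        )
        groups = np.where(high == 1, "high", "low")
        summary, fit = multivariate_report(
            clinical, _preds_from(clinical, groups)
        )
        beta = np.log(summary.loc["risk_group_high", "hazard_ratio"])
        se = fit.standard_errors["risk_group_high"]
        assert abs(beta - 1.2) < 1.96 * se

    def test_duplicated_covariate_rejected(self, cohort):
        clinical, _ = cohort
        dup = clinical.data.copy()
        dup["grade"] = dup["age_years"]  # exact duplicate under new name
        with pytest.raises(ValueError, match="collinear"):
            multivariate_report(
                pg.ClinicalTable(dup),
                _preds_from(clinical, ["high", "low"]
                            * (clinical.n_samples // 2)),
            )

    def test_report_is_deterministic(self, cohort):
        clinical, truth = cohort
        groups = truth.true_risk_half.loc[clinical.sample_ids]
        preds = _preds_from(clinical, groups)
        a, _ = multivariate_report(clinical, preds)
        b, _ = multivariate_report(clinical, preds)
        pd.testing.assert_frame_equal(a, b)
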