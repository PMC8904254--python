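import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunotrack import (
    CohortModel,
    DegenerateInputError,
    ValidationError,
    binomial_ci,
    exact_match,
    gen_cohort,
    km_estimate,
    response_tally,
    reverse_km_followup,
    weighted_cox,
    weighted_logistic,
)


class TestBinomialCi:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [(24, 30, 0.627, 0.905), (13, 30, 0.274, 0.608), (8, 13, 0.355, 0.823)],
    )
    def test_wilson_printed_values(self, x, n, lo, hi):
        got = binomial_ci(x, n, method="wilson")
        assert got[0] == pytest.approx(lo, abs=5e-4)
        assert got[1] == pytest.approx(hi, abs=5e-4)

    def test_clopper_pearson_all_successes_closed_form(self):
        lo, hi = binomial_ci(30, 30, method="clopper_pearson")
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 30), rel=1e-9)

    @pytest.mark.parametrize(
        "x,n,lo,hi", [(23, 29, 0.610, 0.904), (12, 29, 0.252, 0.596)]
    )
    def test_logit_wald_printed_values(self, x, n, lo, hi):
        got = binomial_ci(x, n, method="logit_wald")
        assert got[0] == pytest.approx(lo, abs=5e-4)
        assert got[1] == pytest.approx(hi, abs=5e-4)

    def test_logit_wald_degenerate(self):
        with pytest.raises(DegenerateInputError):
            binomial_ci(0, 10, method="logit_wald")

    @pytest.mark.parametrize("p_true", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_coverage_by_exact_enumeration(self, p_true):
        # exact coverage at n=30: CP >= nominal; Wilson dips to ~0.9298 at
        # p=0.3/0.7, so its floor is 0.92
        n = 30
        for method, floor in (("clopper_pearson", 0.95), ("wilson", 0.92)):
            cover = 0.0
            for x in range(n + 1):
                lo, hi = binomial_ci(x, n, method=method)
                if lo <= p_true <= hi:
                    cover += stats.binom.pmf(x, n, p_true)
            assert cover >= floor - 1e-9


class TestResponseTally:
    def test_orr_combines_cr_pr(self):
        resp = ["CR"] * 13 + ["PR"] * 11 + ["PD"] * 6
        tally = response_tally(resp).set_index("category")
        assert tally.loc["ORR", "count"] == 24
        assert tally.loc["ORR", "rate"] == pytest.approx(0.8)
        assert tally.loc["CR", "rate"] == pytest.approx(13 / 30)

    def test_boundary_rates(self):
        t0 = response_tally(["PD"] * 5).set_index("category")
        assert t0.loc["ORR", "rate"] == 0.0
        t1 = response_tally(["CR"] * 5).set_index("category")
        assert t1.loc["ORR", "rate"] == 1.0


class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival_at(2.5) == pytest.approx(0.5)
        assert curve.median == 2.0

    def test_censoring_hand_product_limit(self):
        # times (1, 2+, 3, 4): S(3) = 0.75 * (1 - 1/2) = 0.375
        curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        assert curve.survival_at(3) == pytest.approx(0.375)

    def test_all_censored_median_not_reached(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert np.isinf(curve.median)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, 40)
        curve = km_estimate(times, np.ones(40))
        for t in (np.quantile(times, 0.25), np.quantile(times, 0.6)):
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])

    def test_survival_nonincreasing_starts_at_one(self, rng):
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        assert curve.survival[0] <= 1.0 + 1e-12
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestReverseKm:
    def test_no_deaths_median_followup(self):
        # all reverse-events at 10/20/30/40: S(20)=0.5 -> median 20
        assert reverse_km_followup([10, 20, 30, 40], [0, 0, 0, 0]) == 20.0

    def test_all_deaths_not_estimable(self):
        assert np.isinf(reverse_km_followup([3, 5, 8], [1, 1, 1]))

    def test_single_patient(self):
        assert reverse_km_followup([12.0], [0]) == 12.0


def small_cohort():
    cases = pd.DataFrame(
        {
            "patient_id": ["t1", "t2", "t3"],
            "arm": "trial",
            "age_group": ["<=70", "<=70", ">70"],
            "sex": ["male", "male", "female"],
            "ldh": ["normal", "normal", "elevated"],
            "m_stage": ["M1c", "M1c", "M1a"],
            "braf": ["mutated", "mutated", "wild type"],
            "pdl1": ["<1%", "<1%", ">=1%"],
        }
    )
    controls = pd.DataFrame(
        {
            "patient_id": [f"c{i}" for i in range(5)],
            "arm": "control",
            "age_group": ["<=70"] * 4 + [">70"],
            "sex": ["male"] * 4 + ["male"],
            "ldh": ["normal"] * 4 + ["normal"],
            "m_stage": ["M1c"] * 4 + ["M1b"],
            "braf": ["mutated"] * 4 + ["wild type"],
            "pdl1": ["<1%"] * 4 + ["<1%"],
        }
    )
    return cases, controls


class TestExactMatch:
    def test_weights_are_case_over_control_count(self):
        cases, controls = small_cohort()
        cohort = exact_match(cases, controls)
        # combination with 2 cases and 4 controls -> each control weight 0.5
        assert len(cohort.cases) == 2
        assert cohort.controls["weight"].tolist() == [0.5] * 4

    def test_unique_combination_case_unmatched(self):
        cases, controls = small_cohort()
        cohort = exact_match(cases, controls)
        assert cohort.unmatched_cases["patient_id"].tolist() == ["t3"]

    def test_one_to_one_gives_unit_weights(self):
        cases, controls = small_cohort()
        cohort = exact_match(cases.iloc[:1], controls.iloc[:1])
        assert cohort.controls["weight"].tolist() == [1.0]

    def test_no_match_rejected(self):
        cases, controls = small_cohort()
        with pytest.raises(ValidationError):
            exact_match(cases.iloc[2:3], controls)

    def test_incomplete_covariates_excluded(self):
        cases, controls = small_cohort()
        cases.loc[0, "ldh"] = np.nan
        cohort = exact_match(cases, controls)
        assert "t1" in set(cohort.excluded["patient_id"])

    def test_control_filter_applied(self):
        cases, controls = small_cohort()
        cohort = exact_match(cases, controls, control_filter=lambda r: r["patient_id"] != "c0")
        assert len(cohort.controls) == 3
        assert cohort.controls["weight"].tolist() == [2 / 3] * 3

    def test_weighted_distribution_matches_cases_on_random_cohorts(self):
        from immunotrack.clinical import MATCHING_COVARIATES

        for seed in range(5):
            df = gen_cohort(CohortModel(seed=seed), 25, 120)
            cohort = exact_match(df[df.arm == "trial"], df[df.arm == "control"])
            key_cases = cohort.cases[MATCHING_COVARIATES].apply(tuple, axis=1)
            key_ctrl = cohort.controls[MATCHING_COVARIATES].apply(tuple, axis=1)
            case_dist = key_cases.value_counts()
            ctrl_mass = cohort.controls.groupby(key_ctrl)["weight"].sum()
            assert set(case_dist.index) == set(ctrl_mass.index)
            for combo, n_cases in case_dist.items():
                assert ctrl_mass[combo] == pytest.approx(n_cases, abs=1e-12)


class TestWeightedLogistic:
    def _frame(self, x_trial, n_trial, x_ctrl, n_ctrl):
        return pd.DataFrame(
            {
                "arm": ["trial"] * n_trial + ["control"] * n_ctrl,
                "response": (["CR"] * x_trial + ["PD"] * (n_trial - x_trial)
                             + ["PR"] * x_ctrl + ["PD"] * (n_ctrl - x_ctrl)),
                "weight": 1.0,
            }
        )

    def test_or_matches_2x2_closed_form(self):
        out = weighted_logistic(self._frame(23, 29, 10, 29))
        assert out["or"] == pytest.approx((23 * 19) / (6 * 10), rel=1e-6)

    def test_fitted_rate_and_logit_wald_ci(self):
        out = weighted_logistic(self._frame(23, 29, 10, 29))
        trial = out["rates"]["trial"]
        assert trial["rate"] == pytest.approx(23 / 29, rel=1e-6)
        assert trial["ci"][0] == pytest.approx(0.610, abs=5e-4)
        assert trial["ci"][1] == pytest.approx(0.904, abs=5e-4)

    def test_equal_rates_or_one(self):
        out = weighted_logistic(self._frame(10, 20, 10, 20))
        assert out["or"] == pytest.approx(1.0, abs=1e-8)
        assert out["p_value"] > 0.9

    def test_separation_sentinel(self):
        out = weighted_logistic(self._frame(20, 20, 5, 20))
        assert out["separation"] and np.isinf(out["or"])

    def test_fitted_rates_equal_weighted_proportions(self):
        df = gen_cohort(CohortModel(seed=3), 30, 150)
        cohort = exact_match(df[df.arm == "trial"], df[df.arm == "control"])
        out = weighted_logistic(cohort)
        frame = cohort.to_frame()
        frame["y"] = frame["response"].isin(["CR", "PR"]).astype(float)
        for arm in ("trial", "control"):
            sub = frame[frame.arm == arm]
            emp = np.average(sub["y"], weights=sub["weight"])
            assert out["rates"][arm]["rate"] == pytest.approx(emp, abs=1e-6)


class TestWeightedCox:
    def test_identical_arms_hr_one(self, rng):
        t = rng.exponential(10, 60)
        e = np.ones(60, dtype=int)
        df = pd.DataFrame(
            {"arm": ["trial"] * 30 + ["control"] * 30,
             "pfs_months": np.concatenate([t[:30], t[:30]]),
             "pfs_event": 1, "weight": 1.0}
        )
        out = weighted_cox(df)
        assert out["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_events_in_arm_rejected(self):
        df = pd.DataFrame(
            {"arm": ["trial"] * 5 + ["control"] * 5,
             "pfs_months": range(1, 11),
             "pfs_event": [1] * 5 + [0] * 5, "weight": 1.0}
        )
        with pytest.raises(ValidationError):
            weighted_cox(df)
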