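import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from nphtest._cox import (
    CoxConvergenceError,
    cox_fit_binary,
    cox_score_chi2,
    grambsch_therneau_chi2,
)
from nphtest.core import SurvivalDataset, build_risk_table, km_estimate
from nphtest.simulate import (
    PiecewiseHREffect,
    low_event_rate_preset,
    sample_trial,
)
from nphtest.statistics import (
    combined_test,
    joint_test,
    run_tests,
    versatile_test,
    weighted_combined_test,
)

from _oracles import combined_statistic_naive, max_abs_trivariate_mc


def _tie_free_dataset(seed, n=120):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0, n)
    c = rng.uniform(0.5, 2.5, n)
    return SurvivalDataset(
        np.minimum(t, c), (t <= c).astype(int), np.repeat([0, 1], n // 2)
    )


class TestJoint:
    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_components_match_lifelines_on_tie_free_data(self, seed):
        # lifelines uses Efron ties, identical to Breslow when times are distinct
        d = _tie_free_dataset(seed)
        table = build_risk_table(d)
        beta = cox_fit_binary(table)
        df = pd.DataFrame({"time": d.time, "event": d.event, "arm": d.arm})
        cph = CoxPHFitter().fit(df, "time", "event", formula="arm")
        assert beta == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        for transform in ("identity", "rank"):
            ref = proportional_hazard_test(
                cph, df, time_transform=transform
            ).summary["test_statistic"].iloc[0]
            mine = grambsch_therneau_chi2(table, beta, transform)
            assert mine == pytest.approx(ref, rel=1e-5)

    def test_score_component_from_scratch(self, make_random_dataset):
        # independent naive evaluation of U(0)^2 / I(0)
        for seed in range(10):
            d = make_random_dataset(seed)
            table = build_risk_table(d)
            u = i = 0.0
            for t in table.time:
                at = d.time >= t
                n1, n = d.arm[at].sum(), at.sum()
                dd = ((d.time == t) & (d.event == 1)).sum()
                d1 = ((d.time == t) & (d.event == 1) & (d.arm == 1)).sum()
                u += d1 - dd * n1 / n
                i += dd * (n1 / n) * (1 - n1 / n)
            assert cox_score_chi2(table) == pytest.approx(u * u / i)

    def test_sum_of_components_and_reference_distribution(self):
        d = _tie_free_dataset(11)
        r = joint_test(d)
        assert r.statistic == pytest.approx(
            r.details["chi2_cox"] + r.details["chi2_gt"]
        )
        assert r.p_value == pytest.approx(stats.chi2.sf(r.statistic, 2))

    def test_gt_component_has_null_mean_about_one(self):
        dist, cens = low_event_rate_preset()
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(400):
            d = sample_trial(900, dist, PiecewiseHREffect.null(), cens, rng=rng)
            vals.append(joint_test(d).details["chi2_gt"])
        assert 0.75 < np.mean(vals) < 1.25

    def test_monotone_likelihood_errors(self):
        d = SurvivalDataset(
            [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [1, 1, 0, 0]
        )
        with pytest.raises(CoxConvergenceError):
            joint_test(d)


class TestCombinedPermutation:
    def _six_subjects(self):
        return SurvivalDataset(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([1, 1, 1, 1, 1, 0]),
            np.array([1, 0, 1, 0, 1, 0]),
        )

    def test_exact_p_matches_exhaustive_oracle(self):
        d = self._six_subjects()
        grid = [2.0, 4.0]
        r = combined_test(d, grid=grid, exact=True)
        m_obs = combined_statistic_naive(d.time, d.event, d.arm, grid)
        assert r.statistic == pytest.approx(m_obs)
        # enumerate all 20 assignments of 3 research labels with the oracle
        from itertools import combinations

        ms = []
        for pos in combinations(range(6), 3):
            arm = np.zeros(6, dtype=int)
            arm[list(pos)] = 1
            ms.append(combined_statistic_naive(d.time, d.event, arm, grid))
        p_oracle = np.mean(np.array(ms) >= m_obs - 1e-12)
        assert r.p_value == pytest.approx(p_oracle)
        assert r.details["permutations"] == 20

    def test_duplicated_arms_are_unremarkable(self):
        # arms identical as multisets: the observed labeling is exchangeable
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 1, 0] * 2)
        arm = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        d = SurvivalDataset(t, e, arm)
        r = combined_test(d, grid=[2.0, 3.0], exact=True)
        assert r.p_value >= 0.5
        rw = weighted_combined_test(d, grid=[2.0, 3.0], exact=True)
        assert rw.p_value >= 0.5

    def test_seeded_reproducibility(self, make_random_dataset):
        d = make_random_dataset(3)
        r1 = combined_test(d, permutations=300, seed=9)
        r2 = combined_test(d, permutations=300, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.details["exceedances"] == r2.details["exceedances"]

    def test_p_estimator_never_zero(self, make_random_dataset):
        d = make_random_dataset(8)
        r = combined_test(d, permutations=150, seed=0)
        assert r.p_value >= 1.0 / 151

    def test_wc_exact_small_case(self):
        d = self._six_subjects()
        r = weighted_combined_test(d, grid=[3.0], exact=True)
        assert 0.0 < r.p_value <= 1.0
        assert r.details["permutations"] == 20

    def test_grid_validation(self, make_random_dataset):
        d = make_random_dataset(1)
        with pytest.raises(ValueError, match="empty"):
            combined_test(d, grid=[], permutations=100, seed=0)
        with pytest.raises(ValueError, match="follow-up"):
            combined_test(d, grid=[d.time.max() * 2], permutations=100, seed=0)


class TestVersatile:
    def test_single_event_collapses_to_normal(self):
        d = SurvivalDataset([1.0, 2.0, 3.0], [1, 0, 0], [1, 0, 1])
        table = build_risk_table(d)
        km = km_estimate(d)
        r = versatile_test(table, km, "vwlr2")
        # one event time: all weight vectors proportional, p = 2(1 - Phi(z))
        assert r.p_value == pytest.approx(2 * stats.norm.sf(r.statistic))

    @pytest.mark.parametrize("variant", ["vwlr", "vwlr2"])
    def test_p_against_trivariate_mc(self, variant):
        d = _tie_free_dataset(17, n=30)
        table = build_risk_table(d)
        km = km_estimate(d)
        r = versatile_test(table, km, variant)
        corr = r.details["correlation"]
        mc = max_abs_trivariate_mc(r.statistic, corr, n_draws=200_000, seed=5)
        se = np.sqrt(mc * (1 - mc) / 200_000)
        assert abs(r.p_value - mc) < 4 * se + 1e-4

    def test_p_between_min_component_and_bonferroni(self, make_random_dataset):
        for seed in range(10):
            d = make_random_dataset(seed)
            table = build_risk_table(d)
            km = km_estimate(d)
            r = versatile_test(table, km, "vwlr")
            comp_p = [
                2 * stats.norm.sf(abs(z)) for z in r.details["z_components"].values()
            ]
            assert min(comp_p) - 1e-10 <= r.p_value <= 3 * min(comp_p) + 1e-10


class TestNineTestContract:
    def test_label_swap_leaves_all_p_values_unchanged(self, make_random_dataset):
        d = make_random_dataset(12)
        a = run_tests(d, permutations=200, seed=4)
        b = run_tests(d.swap_arms(), permutations=200, seed=4)
        for name in a:
            assert a[name].p_value == pytest.approx(b[name].p_value), name

    def test_unknown_test_name_rejected(self, make_random_dataset):
        with pytest.raises(ValueError, match="unknown"):
            run_tests(make_random_dataset(0), ["lr", "nope"])
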