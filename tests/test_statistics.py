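import numpy as np
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats

from nphtest.core import SurvivalDataset, build_risk_table, km_estimate
from nphtest.statistics import (
    fh_weights,
    sup_brownian_pvalue,
    sup_logrank,
    vwlr2_weights,
    weighted_logrank,
)

from _oracles import weighted_logrank_by_summation


class TestWeights:
    def test_fh_schemes_at_first_event(self, small_mixed_dataset):
        km = km_estimate(small_mixed_dataset)
        early = fh_weights(km, "early")
        late = fh_weights(km, "late")
        assert early[0] == 1.0 and late[0] == 0.0
        assert np.all(fh_weights(km, "lr") == 1.0)

    def test_early_and_late_weights_sum_to_one(self, small_mixed_dataset):
        km = km_estimate(small_mixed_dataset)
        total = fh_weights(km, "early") + fh_weights(km, "late")
        assert np.allclose(total, 1.0)

    def test_vwlr2_rescaling(self):
        # S(t-0) values 1, 0.95, 0.9 with S_min = 0.9: weights 1, 0.5, floor
        km = km_estimate(
            SurvivalDataset(
                np.arange(1.0, 21.0),
                np.array([1, 1] + [0] * 18),
                np.array([0, 1] * 10),
            )
        )
        w = vwlr2_weights(km)
        assert w[0] == 1.0  # numerator equals denominator at the first event
        assert w[-1] == 0.001  # floor is active exactly at S(t-0) = S_min

    def test_vwlr2_interior_value(self):
        class FakeKM:
            left = np.array([1.0, 0.95, 0.9])
            s_min = 0.9

        w = vwlr2_weights(FakeKM())
        assert w[1] == pytest.approx(0.5)

    def test_vwlr2_tends_to_fh_early_as_smin_vanishes(self):
        rng = np.random.default_rng(4)
        n = 400
        t = rng.exponential(1.0, n)  # high event rate: nearly everyone fails
        d = SurvivalDataset(t, np.ones(n), np.repeat([0, 1], n // 2))
        km = km_estimate(d)
        bound = km.s_min / (1.0 - km.s_min) + 0.001
        assert np.max(np.abs(vwlr2_weights(km) - fh_weights(km, "early"))) <= bound


class TestWeightedLogrank:
    def test_single_event_hypergeometric_term(self):
        d = SurvivalDataset([1.0, 2.0], [1, 0], [1, 0])
        r = weighted_logrank(build_risk_table(d))
        assert r.details["U"] == pytest.approx(0.5)
        assert r.details["V"] == pytest.approx(0.25)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(0.3173, abs=1e-4)

    def test_label_swap_flips_sign_keeps_p(self, small_mixed_dataset):
        r = weighted_logrank(build_risk_table(small_mixed_dataset))
        r2 = weighted_logrank(build_risk_table(small_mixed_dataset.swap_arms()))
        assert r2.statistic == pytest.approx(-r.statistic)
        assert r2.p_value == pytest.approx(r.p_value)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_and_lifelines(self, make_random_dataset, seed):
        d = make_random_dataset(seed)
        table = build_risk_table(d)
        km = km_estimate(d)
        for scheme in ("lr", "early"):
            w = fh_weights(km, scheme)
            r = weighted_logrank(table, w)
            u_o, v_o = weighted_logrank_by_summation(
                d.time, d.event, d.arm, dict(zip(table.time, w))
            )
            assert r.details["U"] == pytest.approx(u_o)
            assert r.details["V"] == pytest.approx(v_o)
        m = d.arm == 1
        ref = ll_logrank(d.time[m], d.time[~m], d.event[m], d.event[~m])
        z2 = weighted_logrank(table).statistic ** 2
        assert z2 == pytest.approx(ref.test_statistic, rel=1e-8)

    def test_weight_validation(self, small_mixed_dataset):
        table = build_risk_table(small_mixed_dataset)
        with pytest.raises(ValueError, match="length"):
            weighted_logrank(table, np.ones(2))
        with pytest.raises(ValueError, match="non-negative"):
            weighted_logrank(table, -np.ones(table.n_times))

    def test_degenerate_variance_errors(self, small_mixed_dataset):
        table = build_risk_table(small_mixed_dataset)
        w = np.zeros(table.n_times)
        w[-1] = 1.0  # weight only the last event time
        if table.n[-1] <= 1:
            with pytest.raises(ValueError, match="degenerate"):
                weighted_logrank(table, w)


class TestSupBrownianPvalue:
    def test_boundary_values(self):
        assert sup_brownian_pvalue(0.0) == 1.0
        assert sup_brownian_pvalue(40.0) < 1e-12

    def test_monotone_decreasing(self):
        bs = np.linspace(0.1, 4.0, 30)
        ps = [sup_brownian_pvalue(b) for b in bs]
        assert all(q <= p for p, q in zip(ps, ps[1:]))

    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 3.0])
    def test_agrees_with_theta_function_series(self, b):
        # independent small-b expansion:
        # P(sup|B| < b) = (4/pi) sum (-1)^k/(2k+1) exp(-(2k+1)^2 pi^2/(8 b^2))
        k = np.arange(80)
        inside = (4 / np.pi) * np.sum(
            (-1.0) ** k / (2 * k + 1) * np.exp(-((2 * k + 1) ** 2) * np.pi**2 / (8 * b * b))
        )
        assert sup_brownian_pvalue(b) == pytest.approx(1 - inside, abs=1e-10)


class TestSupLogrank:
    def test_single_event_time_reduces_to_logrank_z(self):
        d = SurvivalDataset([1.0, 1.0, 2.0, 2.0], [1, 1, 0, 0], [0, 1, 0, 1])
        table = build_risk_table(d)
        z = abs(weighted_logrank(table).statistic)
        r = sup_logrank(table)
        assert r.statistic == pytest.approx(z)
        assert r.p_value >= weighted_logrank(table).p_value

    def test_label_swap_invariance(self, small_mixed_dataset):
        p1 = sup_logrank(build_risk_table(small_mixed_dataset)).p_value
        p2 = sup_logrank(
            build_risk_table(small_mixed_dataset.swap_arms())
        ).p_value
        assert p1 == pytest.approx(p2)

    def test_statistic_at_least_final_z(self, make_random_dataset):
        for seed in range(10):
            d = make_random_dataset(seed)
            table = build_risk_table(d)
            assert (
                sup_logrank(table).statistic
                >= abs(weighted_logrank(table).statistic) - 1e-12
            )


class TestTimeTransformInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_rank_tests_invariant_to_monotone_time_transform(
        self, make_random_dataset, seed
    ):
        from nphtest.statistics import versatile_test

        d = make_random_dataset(seed)
        d3 = SurvivalDataset(d.time**3, d.event, d.arm)
        for data in (d,):
            t1, t2 = build_risk_table(d), build_risk_table(d3)
            k1, k2 = km_estimate(d), km_estimate(d3)
            for scheme in ("lr", "early", "late"):
                p1 = weighted_logrank(t1, fh_weights(k1, scheme)).p_value
                p2 = weighted_logrank(t2, fh_weights(k2, scheme)).p_value
                assert p1 == pytest.approx(p2)
            assert sup_logrank(t1).p_value == pytest.approx(sup_logrank(t2).p_value)
            for variant in ("vwlr", "vwlr2"):
                assert versatile_test(t1, k1, variant).p_value == pytest.approx(
                    versatile_test(t2, k2, variant).p_value
                )
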