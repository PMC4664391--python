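"""Distribution fitters, one-way/tornado analysis, PSA and CEAC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bfcea import (
    ceac,
    fit_beta,
    fit_gamma,
    fit_lognormal_from_ci,
    fraction_below_threshold,
    one_way,
    run_psa,
    tornado,
    yll,
)
from bfcea.parameters import DalyParams, default_parameters
from bfcea.sensitivity import PsaResult, sample_parameter_set


class TestFitBeta:
    def test_method_of_moments_example(self):
        a, b = fit_beta(0.33, 0.05)
        assert a == pytest.approx(28.86, abs=0.01)
        assert b == pytest.approx(58.59, abs=0.01)

    @pytest.mark.parametrize("mean, se", [(0.33, 0.05), (0.06, 0.01), (0.9, 0.02)])
    def test_fitted_moments_reproduce_inputs(self, mean, se):
        a, b = fit_beta(mean, se)
        assert a / (a + b) == pytest.approx(mean, abs=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(se, abs=1e-9)

    def test_symmetric_degenerate_limit(self):
        a, b = fit_beta(0.5, 1e-6)
        assert a == pytest.approx(b)
        assert a / (a + b) == pytest.approx(0.5)
        assert a > 1e10

    def test_infeasible_variance(self):
        with pytest.raises(ValueError, match="infeasible"):
            fit_beta(0.5, 0.6)

    def test_mean_bounds(self):
        with pytest.raises(ValueError):
            fit_beta(1.0, 0.1)


class TestFitLognormal:
    def test_partial_breastfeeding_relative_risk(self):
        mu, sigma = fit_lognormal_from_ci(4.43, 1.75, 13.84)
        assert mu == pytest.approx(1.4884, abs=1e-4)
        assert sigma == pytest.approx(0.5276, abs=1e-4)

    def test_point_estimate_preserved(self):
        mu, _ = fit_lognormal_from_ci(2.28, 0.08, 6.55)
        assert math.exp(mu) == pytest.approx(2.28)

    def test_degenerate_ci(self):
        _, sigma = fit_lognormal_from_ci(4.43, 4.43, 4.43)
        assert sigma == 0.0

    def test_non_positive_bounds(self):
        with pytest.raises(ValueError):
            fit_lognormal_from_ci(1.0, 0.0, 2.0)


class TestFitGamma:
    def test_se_equals_mean_convention_gives_exponential(self):
        assert fit_gamma(95, 95) == pytest.approx((1.0, 95.0))

    def test_method_of_moments(self):
        assert fit_gamma(95, 9.5) == pytest.approx((100.0, 0.95))

    def test_non_positive_inputs(self):
        with pytest.raises(ValueError):
            fit_gamma(-1, 1)


class TestFitterSampling:
    def test_large_sample_moments(self):
        """10^6 draws from each fitted distribution reproduce the target
        moments within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        n = 1_000_000

        a, b = fit_beta(0.33, 0.05)
        x = rng.beta(a, b, n)
        assert x.mean() == pytest.approx(0.33, abs=3 * 0.05 / math.sqrt(n))
        assert x.std() == pytest.approx(0.05, rel=0.01)

        shape, scale = fit_gamma(95, 95)
        x = rng.gamma(shape, scale, n)
        assert x.mean() == pytest.approx(95, abs=3 * 95 / math.sqrt(n))
        assert x.std() == pytest.approx(95, rel=0.01)

        mu, sigma = fit_lognormal_from_ci(4.43, 1.75, 13.84)
        x = rng.lognormal(mu, sigma, n)
        assert np.median(x) == pytest.approx(4.43, rel=0.01)
        assert np.quantile(x, 0.975) / np.quantile(x, 0.025) == pytest.approx(
            13.84 / 1.75, rel=0.05
        )


class TestOneWay:
    def test_degenerate_range_zero_swing(self, params):
        res = one_way(params, "daly.discount_rate", 0.03, 0.03, wtp=1653)
        assert res.swing == 0.0

    def test_discount_rate_range_produces_swing(self, params):
        res = one_way(params, "daly.discount_rate", 0.0, 0.06, wtp=1653)
        assert res.swing >= 0
        assert res.output_low != res.output_high

    def test_life_expectancy_monotone_in_yll(self):
        lo = yll(1.0, DalyParams(life_expectancy_years=38))
        hi = yll(1.0, DalyParams(life_expectancy_years=77))
        assert hi > lo

    def test_unknown_param_lists_valid_ids(self, params):
        with pytest.raises(KeyError, match="valid ids"):
            one_way(params, "daly.nope", 0, 1, wtp=100)

    def test_inverted_range_rejected(self, params):
        with pytest.raises(ValueError):
            one_way(params, "daly.discount_rate", 0.06, 0.0, wtp=100)


class TestTornado:
    def test_default_ranges_count_and_shares(self, params):
        results = tornado(params)
        assert len(results) == 8
        assert sum(r.share_pct for r in results) == pytest.approx(100, abs=0.1)
        swings = [r.swing for r in results]
        assert swings == sorted(swings, reverse=True)

    def test_single_parameter_full_share(self, params):
        results = tornado(params, [("daly.discount_rate", 0.0, 0.06)])
        assert len(results) == 1
        assert results[0].share_pct == pytest.approx(100)

    def test_ranking_matches_brute_force(self, params):
        ranges = [
            ("mortality.cumulative_6mo_intervention", 0.001, 0.01),
            ("costs.hospitalised_case", 65.0, 134.0),
            ("daly.discount_rate", 0.0, 0.06),
        ]
        results = tornado(params, ranges)
        singles = {
            pid: one_way(params, pid, lo, hi, params.settings.wtp_per_daly).swing
            for pid, lo, hi in ranges
        }
        expected_order = [
            pid for pid, _ in sorted(singles.items(), key=lambda kv: -kv[1])
        ]
        assert [r.param_id for r in results] == expected_order

    def test_share_permutation_invariance(self, params):
        ranges = [
            ("daly.discount_rate", 0.0, 0.06),
            ("costs.hospitalised_case", 65.0, 134.0),
        ]
        a = tornado(params, ranges)
        b = tornado(params, list(reversed(ranges)))
        assert {r.param_id: pytest.approx(r.share_pct) for r in a} == {
            r.param_id: r.share_pct for r in b
        }

    def test_empty_ranges_rejected(self, params):
        with pytest.raises(ValueError):
            tornado(params, [])


def degenerate_psa(delta_cost, delta_effect, n=100, effect="mebf"):
    draws = pd.DataFrame(
        {
            "draw": range(n),
            "delta_cost": delta_cost,
            "delta_mebf": delta_effect if effect == "mebf" else 0.0,
            "delta_daly": delta_effect if effect == "daly" else 0.0,
        }
    )
    return PsaResult(draws=draws, params=pd.DataFrame(), seed=0, n_draws=n)


class TestPsa:
    def test_same_seed_reproducible(self, params):
        a = run_psa(params, 20, seed=7)
        b = run_psa(params, 20, seed=7)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_different_seeds_differ(self, params):
        a = run_psa(params, 5, seed=1)
        b = run_psa(params, 5, seed=2)
        assert not a.draws.equals(b.draws)

    def test_degenerate_distributions_recover_base_case(self):
        p = default_parameters()
        p.severity.rr_partial_ci = (4.43, 4.43)
        huge_n = {"control": 10**14, "intervention": 10**14}
        zero_cost_se = {
            k: 0.0
            for k in (
                "hfp_per_child",
                "peer_counselling_per_child",
                "hospitalised_case",
                "non_hospitalised_case",
            )
        }
        psa = run_psa(p, 5, seed=0, arm_n=huge_n, cost_se=zero_cost_se)
        for col in ("delta_cost", "delta_mebf", "delta_daly"):
            np.testing.assert_allclose(psa.draws[col], psa.base[col], atol=1e-4)

    def test_sampled_cost_mean_matches_target(self, params):
        psa = run_psa(params, 1000, seed=3)
        costs = psa.params["costs.hospitalised_case"]
        assert costs.mean() == pytest.approx(95, abs=3 * 95 / math.sqrt(len(costs)))

    def test_sampled_probability_rows_valid(self, params):
        _, sampled = sample_parameter_set(
            params, np.random.default_rng(0)
        )
        probs = {k: v for k, v in sampled.items() if k.startswith(("feeding.", "health."))}
        assert all(0 <= v <= 1 for v in probs.values())


class TestCeac:
    def test_break_even_step_at_base_case_icer(self):
        psa = degenerate_psa(137.0, 2.0)
        curve = ceac(psa, [0, 68, 68.5, 69, 200], effect="mebf")
        np.testing.assert_allclose(curve.p_peer_counselling, [0, 0, 0, 1, 1])
        np.testing.assert_allclose(curve.p_peer_counselling + curve.p_hfp, 1.0)

    def test_zero_wtp_with_positive_costs(self):
        psa = degenerate_psa(137.0, 2.0)
        curve = ceac(psa, [0], effect="mebf")
        assert curve.p_peer_counselling[0] == 0.0

    def test_monotone_when_all_effects_positive(self, params):
        psa = run_psa(params, 200, seed=5)
        keep = psa.draws[psa.draws["delta_mebf"] > 0].reset_index(drop=True)
        sub = PsaResult(draws=keep, params=pd.DataFrame(), seed=5, n_draws=len(keep))
        curve = ceac(sub, range(0, 501, 10), effect="mebf")
        assert (np.diff(curve.p_peer_counselling) >= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(degenerate_psa(1, 1), [])


class TestFractionBelowThreshold:
    def test_all_dominant(self):
        psa = degenerate_psa(-10.0, 0.5, effect="daly")
        assert fraction_below_threshold(psa, 100, "daly") == 1.0

    def test_all_dominated(self):
        psa = degenerate_psa(10.0, -0.5, effect="daly")
        assert fraction_below_threshold(psa, 100, "daly") == 0.0

    def test_published_threshold_arithmetic(self):
        # dC 137 vs 1653 * 0.01207 = 19.95: not cost-effective
        psa = degenerate_psa(137.0, 0.01207, effect="daly")
        assert fraction_below_threshold(psa, 1653, "daly") == 0.0
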