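"""Tornado, distributional sampling, PrSA and CEAC."""

import numpy as np
import pytest

from prostate_cea import uncertainty as unc
from prostate_cea.markov import run_cohort
from prostate_cea import economics
from prostate_cea.parameters import Arm, get_param, load_config


class TestDefaultRanges:
    def test_cost_range_is_quarter_of_base(self, params):
        ranges = {r.path: r for r in unc.default_ranges(params)}
        r = ranges["costs.imrt20_cost"]
        assert (r.low, r.high) == (807_135, 1_345_225)

    def test_psa_control_uses_explicit_excursion(self, params):
        ranges = {r.path: r for r in unc.default_ranges(params)}
        r = ranges["clinical.psa_control"]
        assert r.low == 0.80 and r.high == 0.95 and r.basis == "explicit"

    def test_zero_base_gives_flagged_degenerate_range(self, params):
        ranges = {r.path: r for r in unc.default_ranges(params)}
        r = ranges["utilities.dec_gi"]
        assert r.degenerate and r.low == r.high == 0.0

    def test_probability_ranges_clipped(self, params):
        for r in unc.default_ranges(params):
            if not r.path.startswith("costs."):
                assert 0.0 <= r.low <= r.high <= 1.0


class TestOneWayDsa:
    def test_degenerate_range_has_zero_spread(self, params, life_table):
        entries = unc.one_way_dsa(
            params, [unc.ParamRange("utilities.dec_gi", 0.0, 0.0)], 5e6, life_table
        )
        assert entries[0].spread == 0.0

    def test_cycle0_cost_spread_equals_range_width(self, params, life_table):
        # Raising an upfront cost by X lowers INMB by exactly X (undiscounted
        # cycle-0 lump sum): a structural oracle for the DSA loop.
        base = get_param(params, "costs.imrt20_cost")
        r = unc.ParamRange("costs.imrt20_cost", 0.75 * base, 1.25 * base)
        entries = unc.one_way_dsa(params, [r], 5e6, life_table)
        assert entries[0].spread == pytest.approx(0.5 * base, rel=1e-9)
        assert entries[0].inmb_at_low > entries[0].inmb_at_high

    def test_entries_sorted_by_descending_spread(self, params, life_table):
        ranges = unc.default_ranges(params)
        entries = unc.one_way_dsa(params, ranges, 5e6, life_table)
        assert len(entries) == len(ranges)
        spreads = [e.spread for e in entries if not e.failed]
        assert spreads == sorted(spreads, reverse=True)
        assert not any(e.failed for e in entries)


class TestSampling:
    def test_moment_matched_beta_and_gamma(self, params):
        spec = unc.default_uncertainty_spec(params, seed=3)
        rng = np.random.default_rng(3)
        vals = unc.sample_parameter_values(spec, rng, 10_000)
        for dist in spec.parameters:
            draws = vals[dist.path]
            if dist.family == "fixed":
                assert np.all(draws == dist.mean)
                continue
            if dist.family == "beta":
                assert np.all((draws >= 0) & (draws <= 1))
            if dist.family == "gamma":
                assert np.all(draws >= 0)
            se = dist.sd / np.sqrt(draws.size)
            assert abs(draws.mean() - dist.mean) < 3 * se, dist.path

    def test_lognormal_moments(self):
        dist = unc.ParamDist("x", "lognormal", mean=2.0, sd=0.5)
        rng = np.random.default_rng(0)
        mu, sigma = unc._lognormal_moments(dist.mean, dist.sd)
        draws = rng.lognormal(mu, sigma, 200_000)
        assert draws.mean() == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(draws.size))
        assert draws.std() == pytest.approx(0.5, rel=0.02)

    def test_sd_to_zero_limit_degenerates_to_mean(self, params):
        spec = unc.default_uncertainty_spec(params, sd_fraction=1e-6, seed=0)
        rng = np.random.default_rng(0)
        sampled = unc.sample_parameter_set(params, spec, rng)
        for dist in spec.parameters:
            assert get_param(sampled, dist.path) == pytest.approx(dist.mean, rel=1e-4)

    def test_infeasible_beta_moments_name_the_parameter(self):
        with pytest.raises(ValueError, match="infeasible"):
            unc.ParamDist("clinical.salvage_success", "beta", mean=0.5, sd=0.6)

    def test_sampled_sets_always_valid(self, params):
        spec = unc.default_uncertainty_spec(params, seed=11)
        rng = np.random.default_rng(11)
        for _ in range(50):
            sampled = unc.sample_parameter_set(params, spec, rng)
            u = sampled.utilities
            assert u.dec_psa_failure <= u.base_utility
            assert u.dec_urinary <= u.base_utility

    def test_spec_roundtrip_through_yaml(self, params, tmp_path):
        spec = unc.default_uncertainty_spec(params, n_iterations=123, seed=9)
        path = tmp_path / "unc.yaml"
        unc.write_uncertainty_spec(spec, path)
        assert unc.read_uncertainty_spec(path) == spec


class TestPrsa:
    def test_same_seed_reproduces_iterations(self, params, life_table):
        spec = unc.default_uncertainty_spec(params, n_iterations=200, seed=42)
        a = unc.run_prsa(params, spec, 5e6, life_table)
        b = unc.run_prsa(params, spec, 5e6, life_table)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)

    def test_all_fixed_spec_reproduces_base_case(self, params, life_table):
        spec = unc.UncertaintySpec(
            (unc.ParamDist("costs.imrt20_cost", "fixed", 1_076_180.0),),
            n_iterations=5,
            seed=0,
        )
        res = unc.run_prsa(params, spec, 5e6, life_table)
        assert np.ptp(res.delta_cost) == 0 and np.ptp(res.delta_qalys) == 0
        rarp = economics.accumulate(run_cohort(Arm.RARP, params, life_table), Arm.RARP, params)
        imrt = economics.accumulate(run_cohort(Arm.IMRT20, params, life_table), Arm.IMRT20, params)
        assert res.delta_cost[0] == pytest.approx(imrt.total_cost - rarp.total_cost, rel=1e-9)
        assert res.prob_cost_effective_at_wtp in (0.0, 1.0)

    def test_vectorized_engine_matches_per_draw_cohort_route(self, params, life_table):
        """The batch recursion must agree with sampling a ParameterSet per
        iteration and running it through run_cohort/accumulate."""
        spec = unc.default_uncertainty_spec(params, n_iterations=8, seed=5)
        res = unc.run_prsa(params, spec, 5e6, life_table)
        rng = np.random.default_rng(spec.seed)
        vals = unc.sample_parameter_values(spec, rng, spec.n_iterations)
        for i in range(spec.n_iterations):
            p_i = unc._parameter_set_from_draw(params, vals, i)
            rc, rq = unc._reference_arm_totals(Arm.RARP, p_i, life_table)
            ac, aq = unc._reference_arm_totals(Arm.IMRT20, p_i, life_table)
            assert res.delta_cost[i] == pytest.approx(ac - rc, rel=1e-9, abs=1e-4)
            assert res.delta_qalys[i] == pytest.approx(aq - rq, rel=1e-9, abs=1e-10)

    def test_unsupported_switch_falls_back_to_reference_route(self, life_table):
        p = load_config({"settings": {"multiplicative_decrements": True}})
        spec = unc.default_uncertainty_spec(p, n_iterations=3, seed=1)
        res = unc.run_prsa(p, spec, 5e6, life_table)
        assert res.n == 3 and res.n_failed == 0


@pytest.fixture(scope="module")
def prsa_result(params, life_table):
    spec = unc.default_uncertainty_spec(params, n_iterations=2_000, seed=7)
    return unc.run_prsa(params, spec, 5e6, life_table)


class TestCeac:
    def test_point_at_wtp_matches_prsa_probability(self, prsa_result):
        curve = unc.ceac(prsa_result)
        at_wtp = curve.loc[curve.threshold_jpy == prsa_result.wtp, "prob_imrt"].item()
        assert at_wtp == prsa_result.prob_cost_effective_at_wtp

    def test_probabilities_sum_to_one(self, prsa_result):
        curve = unc.ceac(prsa_result)
        np.testing.assert_allclose(curve.prob_imrt + curve.prob_rarp, 1.0, atol=1e-15)
        assert ((curve.prob_imrt >= 0) & (curve.prob_imrt <= 1)).all()

    def test_threshold_zero_counts_cheaper_iterations(self, prsa_result):
        curve = unc.ceac(prsa_result, thresholds=np.array([0.0]))
        assert curve.prob_imrt.iloc[0] == np.mean(prsa_result.delta_cost < 0)

    def test_monotone_when_all_gains_positive(self):
        res = unc.PrSAResult(
            delta_cost=np.array([-10.0, 5.0, 100.0]),
            delta_qalys=np.array([0.1, 0.2, 0.0]),
            wtp=5e6, seed=0, n=3,
        )
        curve = unc.ceac(res)
        assert (np.diff(curve.prob_imrt) >= 0).all()

    def test_recomputation_from_records_is_bit_identical(self, prsa_result, tmp_path):
        import pandas as pd

        path = tmp_path / "iters.csv"
        unc.iterations_to_frame(prsa_result).to_csv(path, index=False)
        rebuilt = unc.prsa_result_from_records(pd.read_csv(path, float_precision="round_trip"), prsa_result.wtp)
        pd.testing.assert_frame_equal(unc.ceac(rebuilt), unc.ceac(prsa_result))
        assert rebuilt.prob_cost_effective_at_wtp == prsa_result.prob_cost_effective_at_wtp

    def test_empty_or_negative_grid_rejected(self, prsa_result):
        with pytest.raises(ValueError):
            unc.ceac(prsa_result, thresholds=np.array([]))
        with pytest.raises(ValueError):
            unc.ceac(prsa_result, thresholds=np.array([-1.0]))
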