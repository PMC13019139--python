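"""Utilities, costs, discounting, ICER/INMB."""

import numpy as np
import pytest

from prostate_cea import economics
from prostate_cea.economics import (
    DOMINANT,
    DOMINATED,
    UNDEFINED,
    accumulate,
    ae_prevalence,
    compare,
    compute_icer,
    compute_inmb,
    cycle_cost,
    state_utility,
)
from prostate_cea.markov import HealthState, run_cohort
from prostate_cea.parameters import Arm, load_config

S = HealthState


class TestAePrevalence:
    def test_imrt_flat_at_reported_value(self, params):
        assert ae_prevalence(Arm.IMRT20, "urinary", 6, params) == 0.031
        assert ae_prevalence(Arm.IMRT20, "sexual", 200, params) == 0.389
        assert ae_prevalence(Arm.IMRT38, "urinary", 6, params) == 0.031

    def test_gi_stops_after_three_years(self, params):
        assert ae_prevalence(Arm.IMRT20, "gi", 36, params) == 0.098
        assert ae_prevalence(Arm.IMRT20, "gi", 37, params) == 0.0
        assert ae_prevalence(Arm.IMRT20, "gi", 48, params) == 0.0

    def test_rarp_month1_reconstruction(self, params):
        # month-1 prevalence = 1-year value + cure-rate share of the complement
        assert ae_prevalence(Arm.RARP, "sexual", 1, params) == pytest.approx(
            0.540 + 0.890 * 0.460, abs=1e-12
        )
        assert ae_prevalence(Arm.RARP, "urinary", 1, params) == pytest.approx(
            0.098 + 0.645 * 0.902, abs=1e-12
        )

    def test_rarp_linear_decline_reaches_one_year_value(self, params):
        assert ae_prevalence(Arm.RARP, "sexual", 12, params) == pytest.approx(0.540, abs=1e-12)
        assert ae_prevalence(Arm.RARP, "sexual", 13, params) == 0.540
        # monotone non-increasing through the recovery year
        vals = [ae_prevalence(Arm.RARP, "urinary", t, params) for t in range(1, 14)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rarp_burden_at_least_imrt_every_cycle(self, params):
        for t in range(1, 241):
            for event in ("urinary", "sexual"):
                assert ae_prevalence(Arm.RARP, event, t, params) >= ae_prevalence(
                    Arm.IMRT20, event, t, params
                )

    def test_no_burden_at_cycle_zero_and_unknown_event(self, params):
        assert ae_prevalence(Arm.RARP, "sexual", 0, params) == 0.0
        with pytest.raises(ValueError, match="unknown"):
            ae_prevalence(Arm.RARP, "cardiac", 3, params)


class TestStateUtility:
    def test_dead_is_zero(self, params):
        assert state_utility(Arm.RARP, S.DEAD, 17, params) == 0.0

    def test_controlled_without_ae_burden_is_base(self, params):
        assert state_utility(Arm.IMRT20, S.PSA_CONTROLLED, 0, params) == 0.90

    def test_additive_decrement_example(self, params):
        # 0.90 - 0.031*0.17 - 0.389*0.11 with zero GI decrement
        assert state_utility(Arm.IMRT20, S.PSA_CONTROLLED, 6, params) == pytest.approx(
            0.85194, abs=1e-12
        )

    def test_failure_and_adt_carry_psa_decrement(self, params):
        u_c = state_utility(Arm.IMRT20, S.PSA_CONTROLLED, 60, params)
        u_f = state_utility(Arm.IMRT20, S.PSA_FAILURE, 60, params)
        u_a = state_utility(Arm.IMRT20, S.ADT, 60, params)
        assert u_f == u_a == pytest.approx(u_c - 0.17, abs=1e-12)

    def test_sexual_weight_scales_decrement(self, params):
        p0 = load_config({"utilities": {"sexual_weight": 0.0}})
        u_full = state_utility(Arm.RARP, S.PSA_CONTROLLED, 6, params)
        u_none = state_utility(Arm.RARP, S.PSA_CONTROLLED, 6, p0)
        assert u_none > u_full
        prev = ae_prevalence(Arm.RARP, "sexual", 6, params)
        assert u_none - u_full == pytest.approx(prev * 0.11, abs=1e-12)

    def test_utility_floors_at_zero(self):
        p = load_config({"utilities": {"base_utility": 0.2, "dec_psa_failure": 0.2,
                                       "dec_urinary": 0.2, "dec_sexual": 0.2}})
        assert state_utility(Arm.RARP, S.ADT, 1, p) == 0.0


class TestCycleCost:
    def test_upfront_costs_at_cycle_zero(self, params):
        one = np.array([1.0, 0, 0, 0, 0])
        assert cycle_cost(Arm.IMRT20, one, 0.0, 0, params) == 1_076_180
        assert cycle_cost(Arm.IMRT38, one, 0.0, 0, params) == 1_445_580
        assert cycle_cost(Arm.RARP, one, 0.0, 0, params) == 1_313_760

    def test_all_dead_costs_nothing(self, params):
        dead = np.array([0, 0, 0, 0, 1.0])
        for arm in Arm:
            assert cycle_cost(arm, dead, 0.0, 10, params) == 0.0

    def test_adt_monthly_cost(self, params):
        occ = np.array([0, 0.9, 0, 0.10, 0])
        assert cycle_cost(Arm.IMRT20, occ, 0.0, 5, params) == pytest.approx(
            0.10 * 224_690 / 12, abs=0.1
        )

    def test_salvage_charged_only_in_rarp_arm(self, params):
        occ = np.array([0, 0.9, 0.1, 0, 0])
        imrt = cycle_cost(Arm.IMRT20, occ, 0.1, 3, params)
        rarp = cycle_cost(Arm.RARP, occ, 0.1, 3, params)
        assert imrt == 0.0
        assert rarp == pytest.approx(0.1 * 1_265_110, abs=1e-9)

    def test_negative_flow_rejected(self, params):
        with pytest.raises(ValueError, match="negative"):
            cycle_cost(Arm.RARP, np.array([0, 1.0, 0, 0, 0]), -0.1, 3, params)


class TestAccumulate:
    def test_undiscounted_year_at_constant_utility(self, zero_mortality_table):
        p = load_config(
            {
                "settings": {"annual_discount": 0.0, "horizon_years": 1},
                "clinical": {
                    "psa_control_imrt": 1.0,
                    "ae_prevalence": {
                        "IMRT": {"urinary": 0, "sexual": 0, "gi": 0},
                    },
                },
            }
        )
        res = accumulate(run_cohort(Arm.IMRT20, p, zero_mortality_table), Arm.IMRT20, p)
        assert res.total_qalys == pytest.approx(0.90, abs=1e-12)
        assert res.total_qalys == res.undiscounted_qalys

    def test_discounted_totals_below_undiscounted(self, params, life_table):
        for arm in Arm:
            res = accumulate(run_cohort(arm, params, life_table), arm, params)
            assert res.total_cost < res.undiscounted_cost
            assert res.total_qalys < res.undiscounted_qalys
            assert 0 <= res.total_qalys <= params.settings.horizon_years

    def test_zero_discount_equates_twins(self, life_table):
        p = load_config({"settings": {"annual_discount": 0.0}})
        res = accumulate(run_cohort(Arm.RARP, p, life_table), Arm.RARP, p)
        assert res.total_cost == pytest.approx(res.undiscounted_cost, rel=1e-12)
        assert res.total_qalys == pytest.approx(res.undiscounted_qalys, rel=1e-12)

    def test_fractionation_differs_only_in_upfront_cost(self, params, life_table):
        r20 = accumulate(run_cohort(Arm.IMRT20, params, life_table), Arm.IMRT20, params)
        r38 = accumulate(run_cohort(Arm.IMRT38, params, life_table), Arm.IMRT38, params)
        assert r38.total_qalys == r20.total_qalys  # bit-identical
        assert r38.total_cost - r20.total_cost == pytest.approx(369_400, abs=1e-3)


class TestIcerInmb:
    def test_printed_ratio_from_table_inputs(self):
        icer = compute_icer(16_724, 0.1164)
        assert isinstance(icer, float)
        # ratio of printed increments; the published 143 685 comes from
        # unrounded internals
        assert icer == pytest.approx(143_677, abs=1.0)

    @pytest.mark.parametrize(
        "dc,dq,expected",
        [
            (100.0, -0.01, DOMINATED),
            (0.0, -0.01, DOMINATED),
            (-5.0, 0.1, DOMINANT),
            (0.0, 0.1, DOMINANT),
            (123.0, 0.0, UNDEFINED),
            (-100.0, -0.01, 10_000.0),  # cheaper and less effective: a ratio
        ],
    )
    def test_dominance_labels(self, dc, dq, expected):
        assert compute_icer(dc, dq) == expected

    def test_inmb_formula(self):
        assert compute_inmb(0.0, 0.0, 5_000_000) == 0.0
        assert compute_inmb(0.1164, 16_724, 5_000_000) == pytest.approx(565_276, abs=1e-6)
        assert compute_inmb(-0.0156, 10_000, 5_000_000) < 0

    def test_inmb_identity_and_sign_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dq = rng.normal(0, 0.2)
            dc = rng.normal(0, 1e5)
            wtp = rng.uniform(1e5, 1e7)
            inmb = compute_inmb(dq, dc, wtp)
            assert inmb == dq * wtp - dc
            icer = compute_icer(dc, dq)
            if dq > 0 and isinstance(icer, float):
                assert (inmb > 0) == (icer < wtp)


def test_compare_identical_results_is_null(params, life_table):
    res = accumulate(run_cohort(Arm.RARP, params, life_table), Arm.RARP, params)
    c = compare(res, res, wtp=5e6)
    assert c.delta_cost == 0 and c.delta_qalys == 0 and c.inmb == 0
    assert c.icer == UNDEFINED


def test_compare_rejects_mismatched_parameter_sets(params, life_table):
    other = load_config({"costs": {"adt_annual": 300_000}})
    a = accumulate(run_cohort(Arm.RARP, params, life_table), Arm.RARP, params)
    b = accumulate(run_cohort(Arm.IMRT20, other, life_table), Arm.IMRT20, other)
    with pytest.raises(ValueError, match="different parameter sets"):
        compare(a, b, wtp=5e6)


def test_utilities_monotone_in_decrements_and_weight(life_table):
    base = load_config({})
    hi = load_config({"utilities": {"dec_sexual": 0.2}})
    lo_w = load_config({"utilities": {"sexual_weight": 0.5}})
    for t in (1, 6, 30, 120):
        u0 = state_utility(Arm.RARP, S.PSA_CONTROLLED, t, base)
        assert state_utility(Arm.RARP, S.PSA_CONTROLLED, t, hi) <= u0
        assert state_utility(Arm.RARP, S.PSA_CONTROLLED, t, lo_w) >= u0
        assert 0 <= u0 <= base.utilities.base_utility
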