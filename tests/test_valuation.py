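"""Discounting, cost accrual, QALY accrual and aggregation."""

import dataclasses

import numpy as np
import pytest

from sbtox import Technique, UtilityCurve, discount_factor, evaluate, run_cohort
from sbtox.markov import FLOW_KEYS, CohortTrace, build_state_space
from sbtox.valuation import _working_annuity, build_streams, summarize

from conftest import set_values, zero_toxicity


def flat_curve(u=1.0):
    return UtilityCurve(np.array([0.0, 110.0]), np.array([u, u]))


def make_trace(flows_per_cycle, n_cycles=4, age=40.0, all_alive=True):
    """Minimal hand-built trace: one start age, everyone in post-treatment."""
    space = build_state_space()
    occupancy = np.zeros((1, n_cycles + 1, space.n))
    occupancy[0, :, space.post_treatment] = 1.0 if all_alive else 0.0
    flows = {key: np.zeros((1, n_cycles)) for key in FLOW_KEYS}
    for key, vals in flows_per_cycle.items():
        flows[key][0, :] = vals
    return CohortTrace(
        space=space,
        start_ages=np.array([age]),
        weights=np.array([1.0]),
        cycle_length=0.5,
        occupancy=occupancy,
        ages=age + 0.5 * np.arange(n_cycles)[None, :],
        active=np.ones((1, n_cycles), dtype=bool),
        flows=flows,
    )


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0.0, 0.03) == 1.0
        assert discount_factor(1.0, 0.03) == pytest.approx(0.970874, abs=1e-6)
        assert discount_factor(2.0, 0.015) == pytest.approx(0.970662, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1.0, -0.03)


class TestUtilityCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            UtilityCurve(np.array([25.0, 50.0]), np.array([0.5, 0.9]))  # increasing
        with pytest.raises(ValueError):
            UtilityCurve(np.array([25.0, 50.0]), np.array([1.2, 0.9]))  # > 1

    def test_age_outside_range_is_an_error(self):
        curve = UtilityCurve(np.array([25.0, 100.0]), np.array([0.9, 0.6]))
        with pytest.raises(ValueError):
            curve(20.0)

    def test_interpolation(self):
        curve = UtilityCurve(np.array([25.0, 100.0]), np.array([0.9, 0.65]))
        assert curve(62.5) == pytest.approx(0.775)


class TestCostAccrual:
    def test_start_of_cycle_discounting_geometric_sum(self, ps):
        """Four equal half-yearly payments at 3%/year, valued at cycle starts."""
        settings = dataclasses.replace(ps.settings, half_cycle="start")
        ps_start = dataclasses.replace(ps, settings=settings)
        from sbtox.event_trees import build_pharma_tree, collapse

        per_event = collapse(build_pharma_tree(ps_start)).expected_cost
        trace = make_trace({"pharma_events": 100.0 / per_event})
        streams = build_streams(trace, ps_start, flat_curve(), include_indirect=False)
        expected = 100.0 * sum(1.03 ** (-0.5 * k) for k in range(4))  # = 391.2835
        assert expected == pytest.approx(391.2835, abs=1e-3)
        assert streams.cost_disc["drugs"].sum() == pytest.approx(expected, rel=1e-9)
        assert streams.cost_raw["drugs"].sum() == pytest.approx(400.0, rel=1e-9)

    def test_one_hospitalization_costs_the_admission_mix(self, ps):
        trace = make_trace({"hosp_events": [1.0, 0, 0, 0]})
        streams = build_streams(trace, ps, flat_curve(), include_indirect=False)
        assert streams.cost_raw["hospitalizations"].sum() == pytest.approx(6296.52, abs=0.01)

    def test_morbidity_productivity_wage_arithmetic(self, ps):
        # per-event sick leave x daily wage x activity rate; the pure event
        # component (14.55 days) prices at 14.55 x 250.118 x 0.751 = 2733.05
        assert 14.55 * ps.base("wage_daily") * ps.value("activity_rate") == pytest.approx(
            2733.05, abs=0.01
        )
        trace = make_trace({"pharma_events": [1.0, 0, 0, 0]})
        streams = build_streams(trace, ps, flat_curve(), include_indirect=True)
        from sbtox.event_trees import build_pharma_tree, collapse

        days = collapse(build_pharma_tree(ps)).expected_sick_days
        expected = days * ps.base("wage_daily") * ps.value("activity_rate")
        assert streams.cost_raw["productivity_morbidity"].sum() == pytest.approx(expected)

    def test_no_sick_leave_beyond_retirement(self, ps):
        trace = make_trace({"pharma_events": [1.0, 0, 0, 0]}, age=70.0)
        streams = build_streams(trace, ps, flat_curve(), include_indirect=True)
        assert streams.cost_raw["productivity_morbidity"].sum() == 0.0

    def test_zero_flows_zero_costs(self, ps, fx):
        trace = run_cohort(zero_toxicity(ps), Technique.CRT3D, 60, fx.life_table)
        streams = build_streams(trace, ps, fx.utilities)
        for component, arr in streams.cost_raw.items():
            assert arr.sum() == 0.0, component


class TestMortalityProductivity:
    def test_working_annuity(self):
        v = 1.0 / 1.03
        expected = (1.0 - v**5) / (1.0 - v)
        assert _working_annuity(np.array([60.0]), 65.0, 0.03, True)[0] == pytest.approx(expected)
        assert _working_annuity(np.array([70.0]), 65.0, 0.03, True)[0] == 0.0
        assert _working_annuity(np.array([60.0]), 65.0, 0.03, False)[0] == 5.0
        # fractional remaining years
        assert _working_annuity(np.array([64.5]), 65.0, 0.03, False)[0] == pytest.approx(0.5)

    def test_death_flow_prices_remaining_earnings(self, ps):
        trace = make_trace({"death_sb": [1.0, 0, 0, 0]}, age=60.0)
        streams = build_streams(trace, ps, flat_curve())
        annual = ps.base("wage_annual") * ps.value("activity_rate")
        assert streams.cost_raw["productivity_mortality"].sum() == pytest.approx(annual * 5.0)


class TestQalys:
    def test_full_health_no_events_half_qaly_per_cycle(self, ps):
        trace = make_trace({})
        streams = build_streams(trace, ps, flat_curve(1.0))
        assert np.allclose(streams.qaly_raw, 0.5)

    def test_event_cycle_loses_relative_disutility(self, ps):
        # one surgical admission under utility 0.8: the event cycle is worth
        # 0.8 x (1 - 0.387) x 0.5 = 0.2452 for that patient-cycle
        surgery_only = set_values(ps, p_surgery_after_hosp=100.0,
                                  p_supportive_after_hosp=0.0,
                                  p_death_after_surgery=0.0,
                                  p_mgmt_after_surgery=100.0)
        trace = make_trace({"hosp_events": [1.0, 0, 0, 0]})
        streams = build_streams(trace, surgery_only, flat_curve(0.8))
        assert streams.qaly_raw[0, 0] == pytest.approx(0.8 * (1 - 0.387) * 0.5)
        assert streams.qaly_raw[0, 1] == pytest.approx(0.8 * 0.5)

    def test_zero_disutility_events_cost_no_qalys(self, ps):
        painless = set_values(ps, disutility_pharma=0.0, disutility_supportive=0.0,
                              disutility_surgery=0.0)
        trace = make_trace({"pharma_events": [1.0, 0, 0, 0], "hosp_events": [1.0, 0, 0, 0]})
        with_dis = build_streams(trace, ps, flat_curve())
        without = build_streams(trace, painless, flat_curve())
        assert without.qaly_raw[0, 0] == pytest.approx(0.5)
        assert with_dis.qaly_raw[0, 0] < without.qaly_raw[0, 0]

    def test_qalys_equal_life_years_at_full_health(self, ps, fx):
        painless = set_values(ps, disutility_pharma=0.0, disutility_supportive=0.0,
                              disutility_surgery=0.0)
        trace = run_cohort(painless, Technique.CRT3D, 60, fx.life_table)
        streams = build_streams(trace, painless, flat_curve(1.0))
        assert np.allclose(streams.qaly_raw, streams.ly_raw)


class TestSummarize:
    def test_totals_and_breakdown_consistency(self, ps, fx):
        trace = run_cohort(ps, Technique.CRT3D, 55, fx.life_table)
        result = evaluate(trace, ps, fx.utilities, Technique.CRT3D)
        assert sum(result.breakdown_discounted.values()) == pytest.approx(
            result.cost_discounted, rel=1e-9
        )
        assert sum(result.breakdown_undiscounted.values()) == pytest.approx(
            result.cost_undiscounted, rel=1e-9
        )

    def test_discounted_below_undiscounted(self, ps, fx):
        trace = run_cohort(ps, Technique.IMRT, 50, fx.life_table)
        result = evaluate(trace, ps, fx.utilities, Technique.IMRT)
        assert result.cost_discounted <= result.cost_undiscounted
        assert result.qaly_discounted <= result.qaly_undiscounted
        for comp in result.breakdown_discounted:
            assert result.breakdown_discounted[comp] <= result.breakdown_undiscounted[comp] + 1e-9
        assert result.qaly_undiscounted <= result.ly_undiscounted

    def test_zero_streams_zero_totals(self, ps, zero_lt):
        trace = make_trace({})
        streams = build_streams(trace, ps, flat_curve(0.0))
        result = summarize(trace, streams)
        assert result.cost_discounted == 0.0
        assert result.qaly_discounted == 0.0

    def test_excluding_indirect_costs_reduces_totals(self, ps, fx):
        trace = run_cohort(ps, Technique.CRT3D, 50, fx.life_table)
        full = evaluate(trace, ps, fx.utilities, include_indirect=True)
        direct = evaluate(trace, ps, fx.utilities, include_indirect=False)
        assert direct.cost_discounted < full.cost_discounted
        assert direct.breakdown_discounted["productivity_morbidity"] == 0.0
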