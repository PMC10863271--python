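"""Cost accrual: medication mix, path costs, strategy cost traces."""

import dataclasses

import numpy as np
import pytest

from ntgcua import (
    HealthState,
    StrategyConfig,
    annual_medication_cost,
    cycle_cost,
    inflate_cost,
    run_cohort,
    run_costing,
)


@pytest.fixture(scope="module")
def costs(params):
    return params.costs


_MONETARY_FIELDS = (
    "annual_dual_therapy",
    "annual_triple_therapy",
    "trabeculectomy",
    "followup_no_progression",
    "followup_progression",
    "first_year_moderate_B",
    "first_year_severe_B",
    "consecutive_year_moderate_B",
    "consecutive_year_severe_B",
)


def _zero_costs(costs):
    """All monetary inputs zeroed; structural rules (mix ratio, dose
    multiplier, failure rate) keep their valid defaults."""
    return dataclasses.replace(costs, **{f: 0.0 for f in _MONETARY_FIELDS})


class TestMedicationCost:
    def test_three_to_one_mix(self, costs):
        # 0.75 * 307.24 + 0.25 * 470.45
        assert annual_medication_cost(costs, 1.0) == pytest.approx(348.04, abs=0.005)

    def test_escalated_dose(self, costs):
        assert annual_medication_cost(costs, 1.5) == pytest.approx(522.06, abs=0.005)

    def test_equal_prices_collapse(self, costs):
        c = dataclasses.replace(
            costs, annual_dual_therapy=100.0, annual_triple_therapy=100.0
        )
        assert annual_medication_cost(c, 1.0) == pytest.approx(100.0)


class TestCycleCost:
    def test_medication_path_mild(self, costs):
        s = StrategyConfig(arm="positive", surgery_rate=0.0)
        got = cycle_cost(HealthState.MILD, 3, s, False, costs)
        assert got == pytest.approx(348.04 + 79.55, abs=0.005)

    def test_medication_path_progressed(self, costs):
        s = StrategyConfig(arm="positive", surgery_rate=0.0)
        got = cycle_cost(HealthState.MODERATE, 3, s, None, costs)
        assert got == pytest.approx(1.5 * 348.0425 + 119.32, abs=0.005)

    def test_surgery_path_entry_cycle(self, costs):
        s = StrategyConfig(arm="positive", surgery_rate=1.0)
        got = cycle_cost(HealthState.MILD, 0, s, False, costs)
        assert got == pytest.approx(530.97 + 79.55, abs=0.005)

    def test_surgery_path_later_cycles_blend_failure_medication(self, costs):
        s = StrategyConfig(arm="positive", surgery_rate=1.0)
        got = cycle_cost(HealthState.MILD, 1, s, False, costs)
        assert got == pytest.approx(79.55 + 0.2 * 348.0425, abs=0.005)

    def test_traditional_stage_entry_vs_consecutive(self, costs):
        s = StrategyConfig(arm="traditional")
        entry = cycle_cost(HealthState.MODERATE, 2, s, None, costs, entering=True)
        stay = cycle_cost(HealthState.MODERATE, 3, s, None, costs)
        assert entry == pytest.approx(381.84 + 119.32)
        assert stay == pytest.approx(254.56 + 119.32)

    def test_dead_state_rejected(self, costs):
        with pytest.raises(ValueError):
            cycle_cost(HealthState.DEAD, 0, StrategyConfig(), False, costs)

    def test_zero_cost_inputs(self, costs):
        zero = _zero_costs(costs)
        for state in (HealthState.MILD, HealthState.SEVERE):
            assert cycle_cost(state, 0, StrategyConfig(surgery_rate=0.5), None, zero) == 0.0


class TestRunCosting:
    def test_zero_costs_zero_total(self, params):
        p = dataclasses.replace(params, costs=_zero_costs(params.costs))
        for arm, s in (
            ("positive", StrategyConfig(surgery_rate=0.5)),
            ("traditional", StrategyConfig(arm="traditional")),
        ):
            trace = run_cohort(p, arm)
            assert run_costing(trace, s, p).total_cost_discounted == 0.0

    def test_blending_linear_in_surgery_rate(self, params):
        trace = run_cohort(params, "positive")
        lo = run_costing(trace, StrategyConfig(surgery_rate=0.0), params)
        hi = run_costing(trace, StrategyConfig(surgery_rate=1.0), params)
        for s in (0.1, 0.25, 0.5, 0.9):
            mid = run_costing(trace, StrategyConfig(surgery_rate=s), params)
            blended = s * hi.per_cycle_cost + (1 - s) * lo.per_cycle_cost
            assert mid.per_cycle_cost == pytest.approx(blended, abs=1e-9)

    def test_monotone_in_surgery_cost_multiplier(self, params):
        trace = run_cohort(params, "positive")
        totals = [
            run_costing(
                trace,
                StrategyConfig(surgery_rate=0.25, surgery_cost_multiplier=m),
                params,
            ).total_cost_discounted
            for m in (1.0, 5.0, 10.0)
        ]
        assert totals[0] < totals[1] < totals[2]

    def test_multiplier_irrelevant_without_surgery(self, params):
        trace = run_cohort(params, "positive")
        t1 = run_costing(
            trace, StrategyConfig(surgery_rate=0.0, surgery_cost_multiplier=1.0), params
        )
        t10 = run_costing(
            trace, StrategyConfig(surgery_rate=0.0, surgery_cost_multiplier=10.0), params
        )
        assert t1.total_cost_discounted == t10.total_cost_discounted

    def test_traditional_first_year_charged_once_per_stage_entry(self, params):
        # total first-year charges equal the discounted-weighted entrant mass;
        # cumulative entrants never exceed one per member per stage
        trace = run_cohort(params, "traditional")
        assert trace.entrants_moderate.sum() <= 1.0 + 1e-12
        assert trace.entrants_severe.sum() <= 1.0 + 1e-12
        strategy = StrategyConfig(arm="traditional")
        base = run_costing(trace, strategy, params)
        p_no_first = dataclasses.replace(
            params,
            costs=dataclasses.replace(
                params.costs, first_year_moderate_B=0.0, first_year_severe_B=0.0
            ),
        )
        no_first = run_costing(trace, strategy, p_no_first)
        expected_first_component = 381.84 * float(
            (trace.weights * (trace.entrants_moderate + trace.entrants_severe)).sum()
        )
        got = base.total_cost_discounted - no_first.total_cost_discounted
        assert got == pytest.approx(expected_first_component, abs=1e-9)

    def test_dead_fraction_accrues_nothing(self, params):
        # costs scale with alive occupancy: an all-dead cohort accrues zero
        trace = run_cohort(params, "positive")
        trace.occupancy[:, :] = 0.0
        trace.occupancy[:, HealthState.DEAD] = 1.0
        trace.entrants_moderate[:] = 0.0
        trace.entrants_severe[:] = 0.0
        out = run_costing(trace, StrategyConfig(surgery_rate=0.5), params)
        assert out.total_cost_discounted == 0.0

    def test_horizon_mismatch_rejected(self, params):
        trace = run_cohort(params, "positive")
        p5 = dataclasses.replace(
            params, econ=dataclasses.replace(params.econ, horizon=5)
        )
        with pytest.raises(ValueError):
            run_costing(trace, StrategyConfig(), p5)

    def test_arm_mismatch_rejected(self, params):
        trace = run_cohort(params, "positive")
        with pytest.raises(ValueError):
            run_costing(trace, StrategyConfig(arm="traditional"), params)

    def test_per_cycle_costs_nonnegative(self, params):
        for arm, s in (
            ("positive", StrategyConfig(surgery_rate=0.5)),
            ("traditional", StrategyConfig(arm="traditional")),
        ):
            trace = run_cohort(params, arm)
            out = run_costing(trace, s, params)
            assert (out.per_cycle_cost >= 0).all()
            assert out.total_cost_discounted == pytest.approx(
                float(np.sum(out.per_cycle_cost))
            )


class TestInflateCost:
    @pytest.mark.parametrize(
        "cost, years, rate, expected",
        [
            (100.0, 0, 0.035, 100.0),
            (100.0, 4, 0.035, 114.75),
            (254.56, 1, 0.035, 263.47),
        ],
    )
    def test_values(self, cost, years, rate, expected):
        assert inflate_cost(cost, years, rate) == pytest.approx(expected, abs=0.005)

    def test_treatment_b_aggregates_are_inflated_2019_prices(self):
        # 345 and 230 USD (2019) carried 3 years at 3.5%/y land on the
        # configured first-year / consecutive-year stage costs
        assert inflate_cost(345.0, 3, 0.035) == pytest.approx(381.84, abs=0.7)
        assert inflate_cost(230.0, 3, 0.035) == pytest.approx(254.56, abs=0.5)

    def test_negative_years(self):
        with pytest.raises(ValueError):
            inflate_cost(100.0, -1, 0.035)
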