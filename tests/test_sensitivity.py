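"""One-way (tornado) analysis and probabilistic sensitivity analysis."""

import numpy as np
import pytest

from ntgcua import (
    ConfigurationError,
    ModelParameters,
    Perturbation,
    PSASpec,
    StrategyConfig,
    TransitionParams,
    compare_strategies,
    default_one_way_plan,
    draw_parameters,
    one_way,
    run_psa,
)
from ntgcua.sensitivity import _COST_FIELDS, _PROB_FIELDS, _UTILITY_FIELDS


@pytest.fixture(scope="module")
def strategy():
    return StrategyConfig(arm="positive", surgery_rate=0.5)


class TestOneWay:
    def test_identity_perturbation_reproduces_base(self, params, strategy):
        base = compare_strategies(params, strategy).icur
        rows = one_way(
            params,
            strategy,
            [Perturbation("noop", ("costs.trabeculectomy",), 1.0, 1.0)],
        )
        assert rows[0].icur_low == pytest.approx(base)
        assert rows[0].icur_high == pytest.approx(base)
        assert rows[0].spread == pytest.approx(0.0)

    def test_unknown_parameter_rejected(self, params, strategy):
        with pytest.raises(ConfigurationError):
            one_way(
                params,
                strategy,
                [Perturbation("bad", ("costs.not_a_field",), 0.8, 1.2)],
            )

    def test_base_case_untouched(self, params, strategy):
        before = params.transitions.p_mild_to_moderate_positive
        one_way(params, strategy, default_one_way_plan())
        assert params.transitions.p_mild_to_moderate_positive == before

    def test_progression_perturbation_moves_both_cost_and_qalys(self, params, strategy):
        rows = one_way(
            params,
            strategy,
            [
                Perturbation(
                    "mild->moderate (positive)",
                    ("transitions.p_mild_to_moderate_positive",),
                    0.5,
                    1.5,
                )
            ],
        )
        row = rows[0]
        # faster progression erodes the positive arm's QALY gain, raising the ICUR
        assert row.icur_high > row.icur_low
        assert row.spread > 0

    def test_published_lever_set_top_three(self, params, strategy):
        # the levers called out in the published tornado lead the ranking
        rows = one_way(params, strategy, default_one_way_plan())
        by_cost_spread = sorted(rows, key=lambda r: -r.cost_spread)
        top3 = {r.parameter for r in by_cost_spread[:3]}
        assert top3 == {
            "surgery rate",
            "mild->moderate transition (positive)",
            "eye-drop cost",
        }

    def test_surgery_rate_lever_spans_the_published_scenarios(self, params, strategy):
        rows = one_way(params, strategy, default_one_way_plan())
        surgery = next(r for r in rows if r.parameter == "surgery rate")
        lo = compare_strategies(params, StrategyConfig(surgery_rate=0.25)).icur
        hi = compare_strategies(params, StrategyConfig(surgery_rate=0.5)).icur
        assert surgery.icur_low == pytest.approx(lo)
        assert surgery.icur_high == pytest.approx(hi)


class TestDrawParameters:
    def test_same_seed_identical(self, params):
        spec = PSASpec(n_samples=1, seed=7)
        d1 = draw_parameters(params, spec, np.random.default_rng(7))
        d2 = draw_parameters(params, spec, np.random.default_rng(7))
        assert d1 == d2

    def test_degenerate_sd_returns_base(self, params):
        spec = PSASpec(n_samples=1, seed=7, sd_fraction=0.0)
        assert draw_parameters(params, spec, np.random.default_rng(7)) is params

    def test_structural_rules_not_drawn(self, params):
        spec = PSASpec(n_samples=1, seed=3)
        d = draw_parameters(params, spec, np.random.default_rng(3))
        assert d.costs.dual_to_triple_ratio == 3.0
        assert d.costs.surgical_failure_rate == 0.20
        assert d.mortality == params.mortality
        assert d.econ == params.econ

    def test_draw_means_recover_base_values(self, params):
        # parameter-level recovery at n = 20,000 within 3 standard errors
        spec = PSASpec(n_samples=20_000, seed=11)
        res = run_psa(params, StrategyConfig(surgery_rate=0.5), spec, keep_draws=True)
        n = spec.n_samples
        for section, names in (
            ("transitions", _PROB_FIELDS),
            ("utilities", _UTILITY_FIELDS),
            ("costs", _COST_FIELDS),
        ):
            for name in names:
                base = params.get_value(f"{section}.{name}")
                se = 0.10 * base / np.sqrt(n)
                assert abs(res.draws[name].mean() - base) < 3 * se, name


class TestRunPSA:
    def test_reproducible_under_fixed_seed(self, params, strategy):
        spec = PSASpec(n_samples=500, seed=99)
        a = run_psa(params, strategy, spec)
        b = run_psa(params, strategy, spec)
        assert a.summary_dict() == b.summary_dict()
        assert (a.results == b.results).all().all()

    def test_degenerate_psa_reproduces_deterministic_result(self, params, strategy):
        spec = PSASpec(n_samples=1, seed=0, sd_fraction=0.0)
        res = run_psa(params, strategy, spec)
        det = compare_strategies(params, strategy)
        assert res.mean_cost_positive == pytest.approx(det.cost_positive, abs=1e-9)
        assert res.mean_cost_traditional == pytest.approx(det.cost_traditional, abs=1e-9)
        assert res.mean_qaly_positive == pytest.approx(det.qaly_positive, abs=1e-12)
        assert res.icur_of_means == pytest.approx(det.icur, abs=1e-6)

    def test_vectorised_path_matches_scalar_engine_draw_by_draw(self, params, strategy):
        spec = PSASpec(n_samples=40, seed=5)
        res = run_psa(params, strategy, spec, keep_draws=True)
        from dataclasses import replace

        from ntgcua.sensitivity import _unchecked_utilities

        for i in range(len(res.results)):
            row = res.draws.iloc[i]
            p_i = replace(
                params,
                transitions=TransitionParams(*(row[k] for k in _PROB_FIELDS)),
                utilities=_unchecked_utilities(*(row[k] for k in _UTILITY_FIELDS)),
                costs=replace(params.costs, **{k: row[k] for k in _COST_FIELDS}),
            )
            det = compare_strategies(p_i, strategy)
            got = res.results.iloc[i]
            assert got["cost_positive"] == pytest.approx(det.cost_positive, abs=1e-8)
            assert got["cost_traditional"] == pytest.approx(det.cost_traditional, abs=1e-8)
            assert got["qaly_positive"] == pytest.approx(det.qaly_positive, abs=1e-10)
            assert got["qaly_traditional"] == pytest.approx(det.qaly_traditional, abs=1e-10)

    def test_icur_of_means_is_ratio_of_mean_increments(self, params, strategy):
        spec = PSASpec(n_samples=2_000, seed=21)
        res = run_psa(params, strategy, spec)
        expected = res.results["delta_cost"].mean() / res.results["delta_qaly"].mean()
        assert res.icur_of_means == pytest.approx(expected, rel=1e-12)
        # and it differs from the mean of per-draw ratios
        per_draw = (res.results["delta_cost"] / res.results["delta_qaly"]).mean()
        assert res.icur_of_means != pytest.approx(per_draw, rel=1e-6)

    def test_utility_ordering_violations_reported_not_suppressed(self, params, strategy):
        # independent 10%-SD Beta margins invert the mild/moderate ordering
        # in a sizeable minority of draws; the fraction is surfaced
        spec = PSASpec(n_samples=5_000, seed=13)
        res = run_psa(params, strategy, spec, keep_draws=True)
        frac = res.utility_ordering_violation_fraction
        observed = float(
            (
                (res.draws["u_moderate"] > res.draws["u_mild"])
                | (res.draws["u_severe"] > res.draws["u_moderate"])
            ).mean()
        )
        assert frac == pytest.approx(observed)
        assert 0.05 < frac < 0.75

    def test_surgery_cost_multiplier_scenarios_raise_mean_cost(self, params):
        spec = PSASpec(n_samples=1_000, seed=8)
        costs = [
            run_psa(
                params,
                StrategyConfig(surgery_rate=0.25, surgery_cost_multiplier=m),
                spec,
            ).mean_cost_positive
            for m in (1.0, 5.0, 10.0)
        ]
        assert costs[0] < costs[1] < costs[2]
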