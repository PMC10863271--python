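"""Model/Results front end for the cost-utility analysis.

``CostUtilityModel`` bundles a validated parameter set with the positive
arm's strategy settings; ``fit()`` evaluates the deterministic Markov
cohort for both arms and returns ``CUAResults`` carrying traces, the
incremental comparison and a formatted summary.  One-way sensitivity and
PSA hang off the model, reusing the fitted base case as their anchor.

    >>> res = CostUtilityModel(surgery_rate=0.5).fit()
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .cohort import CohortTrace, run_cohort
from .costing import CostTrace, StrategyConfig, run_costing
from .economics import CEResult, compare_strategies
from .parameters import ModelParameters, default_parameters, load_parameters
from .sensitivity import (
    PSAResult,
    PSASpec,
    Perturbation,
    TornadoRow,
    default_one_way_plan,
    one_way,
    run_psa,
)

__all__ = ["CostUtilityModel", "CUAResults", "base_case_table"]


class CostUtilityModel:
    """A 10-year NTG treatment decision problem ready to evaluate.

    Parameters
    ----------
    params : ModelParameters, optional
        Validated inputs; the packaged base case when omitted.
    surgery_rate : float
        Fraction of the positive arm receiving trabeculectomy at entry.
    surgery_cost_multiplier : float
        Scenario multiplier on the surgery cost (1, 5 or 10 in the
        published scenarios).
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        surgery_rate: float = 0.0,
        surgery_cost_multiplier: float = 1.0,
    ):
        self.params = params if params is not None else default_parameters()
        self.strategy = StrategyConfig(
            arm="positive",
            surgery_rate=surgery_rate,
            surgery_cost_multiplier=surgery_cost_multiplier,
        )

    @classmethod
    def from_config(cls, path, **strategy_kwargs) -> "CostUtilityModel":
        """Build the model from a JSON/YAML parameter file."""
        return cls(load_parameters(path), **strategy_kwargs)

    def fit(self) -> "CUAResults":
        """Evaluate both arms deterministically."""
        trace_pos = run_cohort(self.params, "positive")
        trace_trad = run_cohort(self.params, "traditional")
        cost_pos = run_costing(trace_pos, self.strategy, self.params)
        cost_trad = run_costing(
            trace_trad, StrategyConfig(arm="traditional"), self.params
        )
        ce = compare_strategies(self.params, self.strategy)
        return CUAResults(self, ce, trace_pos, trace_trad, cost_pos, cost_trad)

    def one_way(self, plan: Sequence[Perturbation] | None = None) -> list[TornadoRow]:
        """One-way sensitivity analysis around this model's base case."""
        if plan is None:
            plan = default_one_way_plan()
        return one_way(self.params, self.strategy, plan)

    def psa(
        self,
        n_samples: int = 10_000,
        seed: int = 0,
        sd_fraction: float = 0.10,
        keep_draws: bool = False,
    ) -> PSAResult:
        """Probabilistic sensitivity analysis around this model's base case."""
        spec = PSASpec(n_samples=n_samples, seed=seed, sd_fraction=sd_fraction)
        return run_psa(self.params, self.strategy, spec, keep_draws=keep_draws)


class CUAResults:
    """Fitted base case: traces, cost traces and the incremental comparison."""

    def __init__(
        self,
        model: CostUtilityModel,
        ce: CEResult,
        trace_positive: CohortTrace,
        trace_traditional: CohortTrace,
        cost_positive: CostTrace,
        cost_traditional: CostTrace,
    ):
        self.model = model
        self.ce = ce
        self.trace_positive = trace_positive
        self.trace_traditional = trace_traditional
        self.cost_positive = cost_positive
        self.cost_traditional = cost_traditional

    def to_frame(self) -> pd.DataFrame:
        """Two-row strategy table in published column order."""
        ce = self.ce
        icur_repr = ce.icur if ce.icur is not None else float("nan")
        return pd.DataFrame(
            [
                {
                    "strategy": "positive",
                    "average_cost": ce.cost_positive,
                    "incremental_cost": ce.delta_cost,
                    "average_qalys": ce.qaly_positive,
                    "incremental_qalys": ce.delta_qaly,
                    "icur": icur_repr,
                },
                {
                    "strategy": "traditional",
                    "average_cost": ce.cost_traditional,
                    "incremental_cost": 0.0,
                    "average_qalys": ce.qaly_traditional,
                    "incremental_qalys": 0.0,
                    "icur": float("nan"),
                },
            ]
        )

    def trace_frame(self) -> pd.DataFrame:
        """Per-cycle trace of both arms with cost contributions appended."""
        frames = []
        for trace, cost in (
            (self.trace_positive, self.cost_positive),
            (self.trace_traditional, self.cost_traditional),
        ):
            df = trace.to_frame()
            df.insert(0, "arm", trace.arm)
            df["cost_contribution"] = cost.per_cycle_cost
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Formatted strategy comparison (monetary and QALY values to 2 dp)."""
        ce = self.ce
        s = self.model.strategy
        icur_txt = (
            f"{ce.icur:,.2f}" if isinstance(ce.icur, float) else str(ce.icur)
        )
        lines = [
            "Cost-utility comparison: positive vs traditional treatment",
            f"  surgery rate {s.surgery_rate:.0%}, "
            f"surgery cost multiplier {s.surgery_cost_multiplier:g}",
            "",
            f"{'strategy':<14}{'cost ($)':>12}{'QALYs':>10}",
            f"{'positive':<14}{ce.cost_positive:>12,.2f}{ce.qaly_positive:>10.2f}",
            f"{'traditional':<14}{ce.cost_traditional:>12,.2f}{ce.qaly_traditional:>10.2f}",
            "",
            f"  incremental cost  {ce.delta_cost:,.2f}",
            f"  incremental QALYs {ce.delta_qaly:.2f}",
            f"  ICUR ($/QALY)     {icur_txt}",
            f"  WTP class         {ce.wtp_class}",
        ]
        return "\n".join(lines)


def base_case_table(
    params: ModelParameters | None = None,
    surgery_rates: Sequence[float] = (0.0, 0.25, 0.5),
    surgery_cost_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Strategy blocks (one per surgery rate) in published table layout."""
    if params is None:
        params = default_parameters()
    rows = []
    for rate in surgery_rates:
        res = CostUtilityModel(
            params,
            surgery_rate=rate,
            surgery_cost_multiplier=surgery_cost_multiplier,
        ).fit()
        block = res.to_frame()
        block.insert(0, "surgery_rate", rate)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
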