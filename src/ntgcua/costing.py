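"""Strategy-specific cost accrual over the cohort trace.

Two strategies are costed:

* **positive** — intensive IOP-lowering from the mild stage.  A fraction
  ``surgery_rate`` of the cohort receives trabeculectomy at entry (the
  surgery path); the rest stay on topical medication (the medication path).
  Medication is a 3:1 dual:triple mix, escalated to 1.5x the normal dose
  once the disease has progressed.  On the surgery path, 20% of operations
  fail and those patients resume the normal-dose medication mix from the
  following cycle; everyone is followed up annually.  Path costs blend
  linearly in ``surgery_rate``.

* **traditional** — follow-up only while mild; on progression to the
  moderate or severe stage a first-year treatment cost applies (surgery
  plus six weeks of drops, as a stage-level aggregate), then a consecutive-
  year cost, plus the progressed-stage follow-up schedule.

Costs are accrued per cycle boundary with the same discounted half-cycle
weights as QALYs (see :mod:`ntgcua.cohort`), so a one-time entry-cycle
charge such as trabeculectomy carries the boundary-0 weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTrace
from .parameters import CostInputs, HealthState, ModelParameters

__all__ = [
    "StrategyConfig",
    "CostTrace",
    "annual_medication_cost",
    "cycle_cost",
    "run_costing",
    "inflate_cost",
]


@dataclass(frozen=True)
class StrategyConfig:
    """Which arm to cost and, for the positive arm, its surgery settings."""

    arm: str = "positive"
    surgery_rate: float = 0.0
    surgery_cost_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in ("positive", "traditional"):
            raise ValueError(f"arm={self.arm!r}; expected 'positive' or 'traditional'")
        if not 0.0 <= self.surgery_rate <= 1.0:
            raise ValueError(f"surgery_rate={self.surgery_rate} outside [0, 1]")
        if self.surgery_cost_multiplier < 1.0:
            raise ValueError(
                f"surgery_cost_multiplier={self.surgery_cost_multiplier} must be >= 1"
            )


@dataclass
class CostTrace:
    """Per-boundary weighted cost contributions and their discounted total."""

    arm: str
    per_cycle_cost: np.ndarray
    total_cost_discounted: float


def annual_medication_cost(costs: CostInputs, dose_multiplier: float = 1.0) -> float:
    """Expected annual topical-therapy cost under the dual:triple mix.

    ``dose_multiplier x (w * dual + (1-w) * triple)`` with w = 3/4 under the
    default 3:1 dual:triple prescribing ratio.
    """
    w = costs.dual_weight
    mix = w * costs.annual_dual_therapy + (1.0 - w) * costs.annual_triple_therapy
    return dose_multiplier * mix


def _followup(costs: CostInputs, progressed: bool) -> float:
    return costs.followup_progression if progressed else costs.followup_no_progression


def _medication_path_cost(
    state: HealthState, progressed: bool, costs: CostInputs
) -> float:
    dose = costs.dose_multiplier_after_progression if progressed else 1.0
    return annual_medication_cost(costs, dose) + _followup(costs, progressed)


def _surgery_path_cost(
    state: HealthState,
    cycle: int,
    progressed: bool,
    costs: CostInputs,
    multiplier: float,
) -> float:
    if cycle == 0:
        return costs.trabeculectomy * multiplier + _followup(costs, progressed)
    # failed surgeries resume the normal-dose 3:1 mix from the cycle after
    # surgery; successful ones need follow-up only
    fail = costs.surgical_failure_rate
    return _followup(costs, progressed) + fail * annual_medication_cost(costs, 1.0)


def _traditional_cost(
    state: HealthState, entering: bool, costs: CostInputs
) -> float:
    if state == HealthState.MILD:
        return costs.followup_no_progression
    if state == HealthState.MODERATE:
        stage = costs.first_year_moderate_B if entering else costs.consecutive_year_moderate_B
    else:
        stage = costs.first_year_severe_B if entering else costs.consecutive_year_severe_B
    return stage + costs.followup_progression


def cycle_cost(
    state: HealthState,
    cycle: int,
    strategy: StrategyConfig,
    progressed_flag: bool | None,
    costs: CostInputs,
    *,
    entering: bool = False,
) -> float:
    """Per-person cost (USD/year, unweighted) for one state in one cycle.

    ``progressed_flag`` marks a member whose disease has progressed
    persistently (1.5x dosing, progressed follow-up schedule); if ``None``
    it is derived from the state, which is exact for this no-regression
    model.  ``entering`` marks the first cycle spent in a traditional-arm
    stage (first-year vs consecutive-year cost).  Dead members accrue
    nothing and may not be queried.
    """
    if state == HealthState.DEAD:
        raise ValueError("cycle_cost queried for the DEAD state")
    if progressed_flag is None:
        progressed_flag = state != HealthState.MILD
    if strategy.arm == "traditional":
        return _traditional_cost(state, entering, costs)
    med = _medication_path_cost(state, progressed_flag, costs)
    s = strategy.surgery_rate
    if s == 0.0:
        return med
    surg = _surgery_path_cost(
        state, cycle, progressed_flag, costs, strategy.surgery_cost_multiplier
    )
    return (1.0 - s) * med + s * surg


def run_costing(
    trace: CohortTrace, strategy: StrategyConfig, params: ModelParameters
) -> CostTrace:
    """Expected discounted per-person cost of a strategy over a cohort trace.

    Occupancies at each boundary are costed with :func:`cycle_cost`
    (first-entry fractions carrying the traditional arm's first-year cost)
    and weighted by the trace's discounted accrual weights.
    """
    if trace.horizon != params.econ.horizon:
        raise ValueError(
            f"trace horizon {trace.horizon} != parameter horizon {params.econ.horizon}"
        )
    if trace.arm != strategy.arm:
        raise ValueError(f"trace arm {trace.arm!r} != strategy arm {strategy.arm!r}")
    costs = params.costs
    occ = trace.occupancy
    h = trace.horizon
    per_cycle = np.zeros(h + 1)
    for c in range(h + 1):
        total = 0.0
        for state in (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE):
            frac = occ[c, state]
            if frac == 0.0:
                continue
            if strategy.arm == "traditional" and state != HealthState.MILD:
                new = (
                    trace.entrants_moderate[c]
                    if state == HealthState.MODERATE
                    else trace.entrants_severe[c]
                )
                staying = frac - new
                total += new * cycle_cost(state, c, strategy, None, costs, entering=True)
                total += staying * cycle_cost(state, c, strategy, None, costs)
            else:
                total += frac * cycle_cost(state, c, strategy, None, costs)
        per_cycle[c] = trace.weights[c] * total
    return CostTrace(
        arm=strategy.arm,
        per_cycle_cost=per_cycle,
        total_cost_discounted=float(per_cycle.sum()),
    )


def inflate_cost(cost: float, years: int, rate: float) -> float:
    """Inflate a historical cost forward ``years`` years at ``rate``/year."""
    if years < 0:
        raise ValueError(f"years={years} must be >= 0")
    return cost * (1.0 + rate) ** years
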