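"""Incremental cost-utility ratios and willingness-to-pay classification.

The decision statistic is ICUR = dCost / dQALY between the positive and
traditional strategies, judged against 1x and 3x China's per-capita GDP:
below 1x GDP the positive strategy is worthwhile, below 3x GDP it is
acceptable for clinical application, otherwise not acceptable.  When one
strategy is both cheaper and more effective the ratio is replaced by a
dominance label; a zero QALY difference makes the ratio undefined and is
raised, never silently divided.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import run_cohort
from .costing import StrategyConfig, run_costing
from .parameters import ModelParameters

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UndefinedICURError",
    "icur",
    "wtp_classify",
    "CEResult",
    "compare_strategies",
]

DOMINANT = "dominant"
DOMINATED = "dominated"

WORTHWHILE = "worthwhile_1xGDP"
ACCEPTABLE = "acceptable_3xGDP"
NOT_ACCEPTABLE = "not_acceptable"


class UndefinedICURError(ZeroDivisionError):
    """Both strategies gain identical QALYs; the ratio has no value."""


def icur(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-utility ratio, or a dominance label.

    Returns dCost/dQALY (USD per QALY) when the sign pattern admits a
    meaningful ratio; ``"dominant"`` when the positive strategy is cheaper
    and more effective, ``"dominated"`` when costlier and less effective.
    """
    if delta_qaly == 0.0:
        raise UndefinedICURError(
            "delta QALY is zero: ICUR undefined for equally effective strategies"
        )
    if delta_qaly > 0 and delta_cost < 0:
        return DOMINANT
    if delta_qaly < 0 and delta_cost > 0:
        return DOMINATED
    return delta_cost / delta_qaly


def wtp_classify(icur_value: float, gdp: float) -> str:
    """Judge a (positive-incremental) ICUR against GDP-multiple thresholds."""
    if icur_value < gdp:
        return WORTHWHILE
    if icur_value < 3.0 * gdp:
        return ACCEPTABLE
    return NOT_ACCEPTABLE


@dataclass(frozen=True)
class CEResult:
    """Per-arm averages, increments, ICUR and its WTP classification.

    ``icur`` is a USD/QALY ratio, a dominance label, or ``None`` when the
    QALY increment is exactly zero (self-comparison).
    """

    cost_positive: float
    cost_traditional: float
    qaly_positive: float
    qaly_traditional: float
    delta_cost: float
    delta_qaly: float
    icur: float | str | None
    wtp_class: str

    def to_dict(self) -> dict:
        return {
            "cost_positive": self.cost_positive,
            "cost_traditional": self.cost_traditional,
            "qaly_positive": self.qaly_positive,
            "qaly_traditional": self.qaly_traditional,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icur": self.icur,
            "wtp_class": self.wtp_class,
        }


def _assemble(
    cost_pos: float,
    cost_trad: float,
    qaly_pos: float,
    qaly_trad: float,
    gdp: float,
) -> CEResult:
    d_cost = cost_pos - cost_trad
    d_qaly = qaly_pos - qaly_trad
    try:
        ratio = icur(d_cost, d_qaly)
    except UndefinedICURError:
        ratio = None
        wtp = "undefined"
    else:
        wtp = ratio if isinstance(ratio, str) else wtp_classify(ratio, gdp)
    return CEResult(
        cost_positive=cost_pos,
        cost_traditional=cost_trad,
        qaly_positive=qaly_pos,
        qaly_traditional=qaly_trad,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icur=ratio,
        wtp_class=wtp,
    )


def compare_strategies(
    params: ModelParameters, positive: StrategyConfig | None = None
) -> CEResult:
    """Run both arms (cohort + costing) and assemble the incremental result."""
    if positive is None:
        positive = StrategyConfig(arm="positive")
    if positive.arm != "positive":
        raise ValueError("the comparator strategy must be the positive arm")
    traditional = StrategyConfig(arm="traditional")
    trace_pos = run_cohort(params, "positive")
    trace_trad = run_cohort(params, "traditional")
    cost_pos = run_costing(trace_pos, positive, params)
    cost_trad = run_costing(trace_trad, traditional, params)
    return _assemble(
        cost_pos.total_cost_discounted,
        cost_trad.total_cost_discounted,
        trace_pos.qalys_discounted,
        trace_trad.qalys_discounted,
        params.econ.gdp_per_capita,
    )
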