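"""Conversions between multi-year probabilities and constant annual rates.

Under a constant hazard r, the probability of an event within t years is
p = 1 - exp(-r t), so r = -ln(1 - p) / t.  These two maps are how a 5-year
trial progression probability becomes the annual transition probability of a
yearly-cycle Markov model.

Note: a frequently seen shorthand writes the second map as exp(-r t), which
is the probability of *surviving* the interval, not of the event.  A 5-year
probability of 0.20 gives r = 0.04463/y and a 1-year event probability of
0.04365 (~4%); the survival form would give 0.956.  The event form is
implemented here.
"""

from __future__ import annotations

import math

__all__ = ["prob_to_rate", "rate_to_prob"]


def prob_to_rate(p: float, t: float) -> float:
    """Instantaneous annual rate from a probability ``p`` over ``t`` years.

    Parameters
    ----------
    p : probability of the event within ``t`` years, in [0, 1).
    t : length of the interval in years, > 0.

    Returns
    -------
    float
        Constant hazard, events per person-year: ``-ln(1 - p) / t``.
    """
    if t <= 0:
        raise ValueError(f"t={t} must be > 0 years")
    if p == 1.0:
        raise ValueError("p=1 implies an infinite rate")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p={p} outside [0, 1)")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Event probability over ``t`` years from a constant annual rate ``r``.

    Returns ``1 - exp(-r t)``, the complement of interval survival.
    """
    if t <= 0:
        raise ValueError(f"t={t} must be > 0 years")
    if r < 0:
        raise ValueError(f"rate={r} must be >= 0")
    return -math.expm1(-r * t)
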