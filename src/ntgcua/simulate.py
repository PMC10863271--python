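"""Synthetic inputs: parameter presets and individual-level patient streams.

The patient simulator draws each subject's annual state path from exactly
the per-cycle transition matrices the deterministic cohort engine uses, so
its empirical state frequencies converge on the cohort trace -- that is its
role: an independent Monte-Carlo oracle for the deterministic engine.
Surgery assignment (probability = strategy surgery rate) and surgical
failure (probability = the configured failure rate) are drawn per patient.

Patients are homogeneous at entry (age 64, mild stage) like the modelled
cohort; an optional age jitter exists for robustness experiments only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import build_transition_matrix
from .costing import StrategyConfig
from .parameters import (
    HealthState,
    ModelParameters,
    MortalityTable,
    TransitionParams,
    default_parameters,
)

__all__ = [
    "PatientRecord",
    "PatientPanel",
    "PRESETS",
    "generate_parameter_fixture",
    "simulate_patients",
]


def _paper_alternative(base: ModelParameters) -> ModelParameters:
    # alternative positive-arm annual rates derived from a visual-field
    # slope argument: 8.5%/y mild->moderate, 3.5%/y moderate->severe
    return replace(
        base,
        transitions=replace(
            base.transitions,
            p_mild_to_moderate_positive=0.085,
            p_moderate_to_severe_positive=0.035,
        ),
    )


def _zero_progression(base: ModelParameters) -> ModelParameters:
    return replace(
        base,
        transitions=TransitionParams(0.0, 0.0, 0.0, 0.0),
    )


def _high_mortality(base: ModelParameters) -> ModelParameters:
    return replace(
        base,
        mortality=MortalityTable(
            bands=((65, 69, 0.05), (70, 74, 0.08)),
            glaucoma_odds_ratio=1.8,
            apply_odds_ratio=True,
            band_mode="attained",
        ),
    )


PRESETS = {
    "paper_default": lambda base: base,
    "paper_alternative_rates": _paper_alternative,
    "stress_zero_progression": _zero_progression,
    "stress_high_mortality": _high_mortality,
}


def generate_parameter_fixture(preset: str) -> ModelParameters:
    """A fully valid parameter set for a named scenario.

    ``paper_default`` is the base case; ``paper_alternative_rates`` swaps in
    the slope-derived positive-arm progression rates (0.085/0.035);
    ``stress_zero_progression`` and ``stress_high_mortality`` are edge-case
    sets for robustness tests.
    """
    try:
        build = PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        ) from None
    return build(default_parameters())


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: annual state path plus surgery flags."""

    id: int
    state_path: tuple[HealthState, ...]
    age_at_entry: float
    surgery_assigned: bool
    surgery_failed: bool


class PatientPanel:
    """Array-backed sequence of simulated patients.

    ``state_paths`` is an (n, horizon+1) integer array of HealthState codes;
    indexing or iterating yields :class:`PatientRecord` views.
    """

    def __init__(
        self,
        state_paths: np.ndarray,
        ages: np.ndarray,
        surgery_assigned: np.ndarray,
        surgery_failed: np.ndarray,
    ):
        self.state_paths = state_paths
        self.ages = ages
        self.surgery_assigned = surgery_assigned
        self.surgery_failed = surgery_failed

    def __len__(self) -> int:
        return self.state_paths.shape[0]

    def __getitem__(self, i: int) -> PatientRecord:
        return PatientRecord(
            id=int(i),
            state_path=tuple(HealthState(s) for s in self.state_paths[i]),
            age_at_entry=float(self.ages[i]),
            surgery_assigned=bool(self.surgery_assigned[i]),
            surgery_failed=bool(self.surgery_failed[i]),
        )

    def __iter__(self) -> Iterator[PatientRecord]:
        for i in range(len(self)):
            yield self[i]

    def empirical_occupancy(self) -> np.ndarray:
        """(horizon+1, 4) empirical state fractions per cycle boundary."""
        n, width = self.state_paths.shape
        out = np.zeros((width, 4))
        for c in range(width):
            out[c] = np.bincount(self.state_paths[:, c], minlength=4) / n
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per patient-cycle (CSV-exportable)."""
        n, width = self.state_paths.shape
        return pd.DataFrame(
            {
                "patient": np.repeat(np.arange(n), width),
                "cycle": np.tile(np.arange(width), n),
                "state": [
                    HealthState(s).name for s in self.state_paths.ravel()
                ],
                "surgery_assigned": np.repeat(self.surgery_assigned, width),
                "surgery_failed": np.repeat(self.surgery_failed, width),
            }
        )


def simulate_patients(
    params: ModelParameters,
    strategy: StrategyConfig,
    n: int,
    seed: int,
    age_jitter: float = 0.0,
) -> PatientPanel:
    """Sample ``n`` patients' annual transitions from the cohort matrices.

    Each patient starts mild; per cycle the next state is drawn from the
    row of that cycle's arm-specific transition matrix.  Surgery is
    assigned with probability ``strategy.surgery_rate`` (positive arm only)
    and fails with the configured surgical failure rate.  Deterministic
    under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h = params.econ.horizon
    paths = np.zeros((n, h + 1), dtype=np.int8)
    states = np.zeros(n, dtype=np.int8)  # all start MILD
    for c in range(h):
        cum = np.cumsum(build_transition_matrix(params, strategy.arm, c).entries, axis=1)
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int8)
        for s in range(4):
            mask = states == s
            if mask.any():
                nxt[mask] = np.searchsorted(cum[s], u[mask], side="right").astype(np.int8)
        np.clip(nxt, 0, 3, out=nxt)
        states = nxt
        paths[:, c + 1] = states
    if strategy.arm == "positive" and strategy.surgery_rate > 0:
        assigned = rng.random(n) < strategy.surgery_rate
        failed = assigned & (rng.random(n) < params.costs.surgical_failure_rate)
    else:
        assigned = np.zeros(n, dtype=bool)
        failed = np.zeros(n, dtype=bool)
    ages = np.full(n, params.econ.start_age)
    if age_jitter > 0:
        ages = ages + rng.normal(0.0, age_jitter, size=n)
    return PatientPanel(paths, ages, assigned, failed)
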