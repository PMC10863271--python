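"""Model inputs for the normal-tension glaucoma cost-utility model.

All inputs are plain numbers a health economist would read off a parameter
table: annual transition probabilities per treatment arm, state utilities,
age-banded natural mortality with a glaucoma odds ratio, unit costs of
medication / surgery / follow-up, and the economic settings (discount rate,
horizon, cohort entry age, willingness-to-pay anchor).

Every container validates its invariants on construction, configurations
round-trip through JSON or YAML, and the packaged ``defaults.yaml`` encodes
the base-case Chinese NTG parameter set verbatim.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "HealthState",
    "TransitionParams",
    "UtilitySet",
    "MortalityTable",
    "CostInputs",
    "EconomicSettings",
    "ModelParameters",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]


class ConfigurationError(Exception):
    """A configuration file is missing, unparsable, or names unknown keys."""


class ValidationError(ValueError):
    """A parameter violates one of its declared bounds or orderings."""


class HealthState(enum.IntEnum):
    """Disease severity states; integer order encodes severity, DEAD absorbs."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2
    DEAD = 3


#: Alive states in severity order, used for vectorised state arithmetic.
ALIVE_STATES = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class TransitionParams:
    """Annual stage-progression probabilities for both treatment arms.

    The positive arm (intensive medication, optionally trabeculectomy)
    progresses more slowly than the traditional arm, so each positive-arm
    probability must not exceed its traditional counterpart.
    """

    p_mild_to_moderate_positive: float = 0.044
    p_moderate_to_severe_positive: float = 0.018
    p_mild_to_moderate_traditional: float = 0.149
    p_moderate_to_severe_traditional: float = 0.056

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _check(0.0 <= v <= 1.0, f"transitions.{f.name}={v} outside [0, 1]")
        _check(
            self.p_mild_to_moderate_positive <= self.p_mild_to_moderate_traditional,
            "positive-arm mild->moderate probability exceeds traditional arm",
        )
        _check(
            self.p_moderate_to_severe_positive <= self.p_moderate_to_severe_traditional,
            "positive-arm moderate->severe probability exceeds traditional arm",
        )

    def for_arm(self, arm: str) -> tuple[float, float]:
        """(mild->moderate, moderate->severe) annual probabilities for ``arm``."""
        if arm == "positive":
            return self.p_mild_to_moderate_positive, self.p_moderate_to_severe_positive
        if arm == "traditional":
            return (
                self.p_mild_to_moderate_traditional,
                self.p_moderate_to_severe_traditional,
            )
        raise ValueError(f"unknown arm {arm!r}; expected 'positive' or 'traditional'")


@dataclass(frozen=True)
class UtilitySet:
    """Preference weights per health state (QALY weights); DEAD is fixed at 0."""

    u_mild: float = 0.80
    u_moderate: float = 0.75
    u_severe: float = 0.71
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        _check(self.u_dead == 0.0, f"u_dead={self.u_dead} must be 0")
        _check(
            0.0 <= self.u_severe <= self.u_moderate <= self.u_mild <= 1.0,
            "utilities must satisfy 0 <= u_severe <= u_moderate <= u_mild <= 1",
        )

    def as_vector(self) -> tuple[float, float, float, float]:
        return (self.u_mild, self.u_moderate, self.u_severe, self.u_dead)


@dataclass(frozen=True)
class MortalityTable:
    """Age-banded annual natural mortality with a glaucoma odds ratio.

    ``bands`` maps inclusive age ranges to annual death probabilities.  The
    published base case holds the entry band's rate over the whole horizon
    (``band_mode='entry'``) and leaves the odds ratio unapplied
    (``apply_odds_ratio=False``); both behaviours are switchable, see
    :mod:`ntgcua.cohort` for how they enter the transition matrix.
    """

    bands: tuple[tuple[int, int, float], ...] = ((65, 69, 0.00364), (70, 74, 0.00518))
    glaucoma_odds_ratio: float = 1.8
    apply_odds_ratio: bool = False
    band_mode: str = "entry"  # 'entry' | 'attained'

    def __post_init__(self) -> None:
        _check(len(self.bands) >= 1, "mortality.bands must be non-empty")
        for lo, hi, p in self.bands:
            _check(lo <= hi, f"mortality band ({lo}, {hi}) is inverted")
            _check(0.0 < p < 1.0, f"mortality probability {p} outside (0, 1)")
        _check(self.glaucoma_odds_ratio > 0, "glaucoma odds ratio must be > 0")
        if self.band_mode not in ("entry", "attained"):
            raise ValidationError(
                f"mortality.band_mode={self.band_mode!r}; expected 'entry' or 'attained'"
            )

    def band_probability(self, age: float) -> float:
        """Annual death probability for an attained ``age``.

        Ages below the first band fall into the first band (a cohort entering
        at 64 immediately uses the 65-69 rate); ages above the last band are a
        coverage error.
        """
        if age <= self.bands[0][1]:
            return self.bands[0][2]
        for lo, hi, p in self.bands:
            if lo <= age <= hi:
                return p
        raise ConfigurationError(
            f"age {age} not covered by mortality bands "
            f"{[(lo, hi) for lo, hi, _ in self.bands]}"
        )


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (2023 USD) and the dosing/mix rules that combine them.

    ``dual_to_triple_ratio`` is the ratio of patients on dual versus triple
    topical therapy (3 means 3:1, i.e. weight 3/4 on dual).  The dose
    multiplier applies once a patient's disease has progressed persistently.
    """

    annual_dual_therapy: float = 307.24
    annual_triple_therapy: float = 470.45
    trabeculectomy: float = 530.97
    followup_no_progression: float = 79.55
    followup_progression: float = 119.32
    first_year_moderate_B: float = 381.84
    first_year_severe_B: float = 381.84
    consecutive_year_moderate_B: float = 254.56
    consecutive_year_severe_B: float = 254.56
    dual_to_triple_ratio: float = 3.0
    dose_multiplier_after_progression: float = 1.5
    surgical_failure_rate: float = 0.20

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _check(v >= 0.0, f"costs.{f.name}={v} must be >= 0")
        _check(
            0.0 <= self.surgical_failure_rate <= 1.0,
            f"surgical_failure_rate={self.surgical_failure_rate} outside [0, 1]",
        )
        _check(
            self.dose_multiplier_after_progression >= 1.0,
            "dose multiplier after progression must be >= 1",
        )

    @property
    def dual_weight(self) -> float:
        """Fraction of medicated patients on dual therapy (3:1 -> 0.75)."""
        r = self.dual_to_triple_ratio
        return r / (r + 1.0)


@dataclass(frozen=True)
class EconomicSettings:
    """Horizon, discounting, cohort entry and willingness-to-pay settings."""

    discount_rate: float = 0.035
    horizon: int = 10
    start_age: float = 64.0
    cohort_size: int = 100_000
    gdp_per_capita: float = 12_692.90
    half_cycle_correction: bool = True
    half_cycle_method: str = "trapezoid"  # 'trapezoid' | 'midpoint'

    def __post_init__(self) -> None:
        _check(self.discount_rate >= 0.0, "discount_rate must be >= 0")
        _check(self.horizon >= 1, "horizon must be >= 1 year")
        _check(self.cohort_size >= 1, "cohort_size must be >= 1")
        _check(self.gdp_per_capita > 0, "gdp_per_capita must be > 0")
        if self.half_cycle_method not in ("trapezoid", "midpoint"):
            raise ValidationError(
                f"half_cycle_method={self.half_cycle_method!r}; "
                "expected 'trapezoid' or 'midpoint'"
            )


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated input set for one model run."""

    transitions: TransitionParams = field(default_factory=TransitionParams)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    mortality: MortalityTable = field(default_factory=MortalityTable)
    costs: CostInputs = field(default_factory=CostInputs)
    econ: EconomicSettings = field(default_factory=EconomicSettings)

    def replace_value(self, dotted: str, value: Any) -> "ModelParameters":
        """Return a copy with the field at ``dotted`` (e.g.
        ``'transitions.p_mild_to_moderate_positive'``) set to ``value``."""
        section, _, name = dotted.partition(".")
        if not name or not hasattr(self, section):
            raise ConfigurationError(f"unknown parameter path {dotted!r}")
        sub = getattr(self, section)
        if not any(f.name == name for f in fields(sub)):
            raise ConfigurationError(f"unknown parameter path {dotted!r}")
        return replace(self, **{section: replace(sub, **{name: value})})

    def get_value(self, dotted: str) -> Any:
        section, _, name = dotted.partition(".")
        if not name or not hasattr(self, section):
            raise ConfigurationError(f"unknown parameter path {dotted!r}")
        sub = getattr(self, section)
        if not any(f.name == name for f in fields(sub)):
            raise ConfigurationError(f"unknown parameter path {dotted!r}")
        return getattr(sub, name)

    def scale_value(self, dotted: str, factor: float) -> "ModelParameters":
        """Multiplicatively perturb one scalar parameter (one-way sensitivity)."""
        return self.replace_value(dotted, self.get_value(dotted) * factor)


_SECTIONS = ("transitions", "utilities", "mortality", "costs", "econ")
_SECTION_TYPES = {
    "transitions": TransitionParams,
    "utilities": UtilitySet,
    "mortality": MortalityTable,
    "costs": CostInputs,
    "econ": EconomicSettings,
}


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> Iterator[tuple[str, Any]]:
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping):
            yield from _flatten(value, f"{dotted}.")
        else:
            yield dotted, value


def _from_mapping(data: Mapping[str, Any]) -> ModelParameters:
    per_section: dict[str, dict[str, Any]] = {s: {} for s in _SECTIONS}
    for dotted, value in _flatten(data):
        section, _, name = dotted.partition(".")
        if section not in per_section or not name:
            raise ConfigurationError(f"unknown configuration key {dotted!r}")
        cls = _SECTION_TYPES[section]
        if not any(f.name == name for f in fields(cls)):
            raise ConfigurationError(f"unknown configuration key {dotted!r}")
        if name == "bands":
            value = tuple((int(lo), int(hi), float(p)) for lo, hi, p in value)
        per_section[section][name] = value
    kwargs = {s: _SECTION_TYPES[s](**vals) for s, vals in per_section.items()}
    return ModelParameters(**kwargs)


def _to_mapping(params: ModelParameters) -> dict[str, dict[str, Any]]:
    out: dict[str, dict[str, Any]] = {}
    for section in _SECTIONS:
        sub = getattr(params, section)
        sec: dict[str, Any] = {}
        for f in fields(sub):
            v = getattr(sub, f.name)
            if f.name == "bands":
                v = [[lo, hi, p] for lo, hi, p in v]
            sec[f.name] = v
        out[section] = sec
    return out


def load_parameters(path: str | Path) -> ModelParameters:
    """Read and validate a parameter configuration (JSON or YAML).

    Keys may be nested sections or flat dotted paths
    (``transitions.p_mild_to_moderate_positive: 0.044``); omitted keys fall
    back to the packaged base-case defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path} must contain a mapping at top level")
    return _from_mapping(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize ``params`` so that :func:`load_parameters` round-trips."""
    path = Path(path)
    data = _to_mapping(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_parameters() -> ModelParameters:
    """The packaged base-case parameter set (Chinese NTG, 2023 USD)."""
    with resources.as_file(resources.files("ntgcua") / "defaults.yaml") as p:
        return load_parameters(p)


def _isclose(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=1e-12)
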