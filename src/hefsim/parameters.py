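"""Parameter registry for the diabetes/HEF microsimulation.

Every tunable quantity is a :class:`DistributionSpec`: a base-case point value
plus, where the evidence base supports one, a probability distribution used
only by the uncertainty analysis (``hefsim.uncertainty``). The base-case
simulation always uses the point values.

The packaged default configuration (``data/table2_base.yaml``) carries the
full registry: unit costs (2019 USD), epidemiological rates for a Cambodian
cohort aged 25-69, care-delivery probabilities, the eight modelled diabetes
complications, and Health Equity Fund (HEF) scheme parameters.
"""

from __future__ import annotations

import importlib.resources
import math
from enum import Enum
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class Family(str, Enum):
    lognormal = "lognormal"
    beta = "beta"
    gamma = "gamma"
    normal = "normal"
    point = "point"


class DistributionSpec(BaseModel):
    """A parameter: base-case point value plus optional sampling distribution.

    Parameter meaning by family: lognormal ``(mu, sigma)``, beta
    ``(alpha, beta)``, gamma ``(shape, scale)``, normal ``(mean, variance)``.
    The ``point`` family ignores ``p1``/``p2`` and always returns
    ``point_value``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    family: Family = Family.point
    p1: float = 0.0
    p2: float = 0.0
    point_value: float

    @model_validator(mode="before")
    @classmethod
    def _coerce_scalar(cls, v: Any) -> Any:
        # a bare number in the config is shorthand for a point mass
        if isinstance(v, (int, float)):
            return {"family": "point", "point_value": float(v)}
        return v

    @model_validator(mode="after")
    def _check_shape(self) -> "DistributionSpec":
        if self.family in (Family.lognormal, Family.gamma) and self.p2 <= 0:
            raise ValueError(f"{self.family.value} requires p2 > 0, got {self.p2}")
        if self.family is Family.beta and (self.p1 <= 0 or self.p2 <= 0):
            raise ValueError(f"beta requires p1, p2 > 0, got ({self.p1}, {self.p2})")
        if self.family is Family.normal and self.p2 < 0:
            raise ValueError(f"normal requires variance p2 >= 0, got {self.p2}")
        return self

    def mean(self) -> float:
        """Analytic mean of the sampling distribution (point value for point)."""
        if self.family is Family.lognormal:
            return math.exp(self.p1 + self.p2**2 / 2)
        if self.family is Family.beta:
            return self.p1 / (self.p1 + self.p2)
        if self.family is Family.gamma:
            return self.p1 * self.p2
        if self.family is Family.normal:
            return self.p1
        return self.point_value


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from the spec's distribution; the point family is degenerate.

    Normal draws (used for strategy relative risks) are truncated at zero —
    negative relative risks are meaningless.
    """
    if spec.family is Family.point:
        return spec.point_value
    if spec.family is Family.lognormal:
        return float(rng.lognormal(spec.p1, spec.p2))
    if spec.family is Family.beta:
        return float(rng.beta(spec.p1, spec.p2))
    if spec.family is Family.gamma:
        return float(rng.gamma(spec.p1, spec.p2))
    # normal, parameterized (mean, variance), truncated at 0
    return max(0.0, float(rng.normal(spec.p1, math.sqrt(spec.p2))))


def _prob(name: str):  # a probability-valued point parameter
    def check(cls, v: DistributionSpec) -> DistributionSpec:
        if not 0.0 <= v.point_value <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1], got {v.point_value}")
        return v

    return field_validator(name)(classmethod(check))


class CostBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    diagnostics: DistributionSpec
    laboratory: DistributionSpec
    oad_annual: DistributionSpec
    insulin_annual: DistributionSpec
    outpatient_visit: dict[str, DistributionSpec]
    inpatient_per_day: dict[str, DistributionSpec]

    @model_validator(mode="after")
    def _nonneg(self) -> "CostBlock":
        for name, spec in self.iter_specs():
            if spec.point_value < 0:
                raise ValueError(f"cost {name} must be >= 0, got {spec.point_value}")
        return self

    def iter_specs(self) -> Iterator[tuple[str, DistributionSpec]]:
        for f in ("diagnostics", "laboratory", "oad_annual", "insulin_annual"):
            yield f, getattr(self, f)
        for level, spec in self.outpatient_visit.items():
            yield f"outpatient_visit.{level}", spec
        for level, spec in self.inpatient_per_day.items():
            yield f"inpatient_per_day.{level}", spec


class TransportBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    outpatient: DistributionSpec
    inpatient: DistributionSpec


class MortalityBand(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    age_lo: float
    age_hi: float
    male: float = Field(ge=0, le=1)
    female: float = Field(ge=0, le=1)


class PopulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    all_cause_mortality: DistributionSpec
    diabetes_incidence: DistributionSpec
    diabetes_prevalence: DistributionSpec
    diabetes_mortality: DistributionSpec
    income: DistributionSpec
    age_min: float = 25
    age_max: float = 69
    sex_ratio: float = Field(0.5, ge=0, le=1)
    mortality_schedule: list[MortalityBand]

    _v1 = _prob("all_cause_mortality")
    _v2 = _prob("diabetes_incidence")
    _v3 = _prob("diabetes_prevalence")
    _v4 = _prob("diabetes_mortality")

    @field_validator("income")
    @classmethod
    def _income_positive(cls, v: DistributionSpec) -> DistributionSpec:
        if v.point_value <= 0:
            raise ValueError("income must be positive")
        return v


COMPLICATION_NAMES = (
    "nephropathy",
    "retinopathy",
    "neuropathy",
    "angina_pectoris",
    "pvd",
    "mi",
    "stroke",
    "heart_failure",
)


class ComplicationProfile(BaseModel):
    """One of the eight modelled diabetes complications.

    ``acute`` complications (MI, stroke) apply their case fatality once, in
    the event year, then persist as chronic sequelae; chronic ones apply it
    every year while active. ``cost_unit`` per_day costs are annualized for
    chronic outpatient therapy and multiplied by length of stay for inpatient
    episodes. The lognormal sampling distributions of per-day costs are on
    the annualized (x365) scale.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)
    name: str
    incidence: float = Field(ge=0, le=1)
    rr_therapy: float = Field(gt=0, le=1)
    disability_weight: float = Field(ge=0, le=1)
    case_fatality: float = Field(ge=0, le=1)
    cost: DistributionSpec
    cost_unit: str  # per_day | per_year
    cost_setting: str  # inpatient | outpatient
    acute: bool

    @field_validator("name")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in COMPLICATION_NAMES:
            raise ValueError(f"unknown complication {v!r}; expected one of {COMPLICATION_NAMES}")
        return v

    @field_validator("cost_unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        if v not in ("per_day", "per_year"):
            raise ValueError(f"cost_unit must be per_day or per_year, got {v!r}")
        return v

    @field_validator("cost_setting")
    @classmethod
    def _setting(cls, v: str) -> str:
        if v not in ("inpatient", "outpatient"):
            raise ValueError(f"cost_setting must be inpatient or outpatient, got {v!r}")
        return v

    @field_validator("cost")
    @classmethod
    def _cost_nonneg(cls, v: DistributionSpec) -> DistributionSpec:
        if v.point_value < 0:
            raise ValueError("complication cost must be >= 0")
        return v


class CareBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    p_diagnosis: DistributionSpec
    p_outpatient_non_hef: DistributionSpec
    p_outpatient_hef: DistributionSpec
    p_inpatient: DistributionSpec
    provider_shares: dict[str, DistributionSpec]
    p_oad: DistributionSpec
    p_insulin: DistributionSpec
    p_combo: DistributionSpec
    p_oad_to_insulin: DistributionSpec
    p_adherence: DistributionSpec
    rr_diet: DistributionSpec
    los_days: DistributionSpec

    _v1 = _prob("p_diagnosis")
    _v2 = _prob("p_outpatient_non_hef")
    _v3 = _prob("p_outpatient_hef")
    _v4 = _prob("p_inpatient")
    _v5 = _prob("p_oad")
    _v6 = _prob("p_insulin")
    _v7 = _prob("p_combo")
    _v8 = _prob("p_oad_to_insulin")
    _v9 = _prob("p_adherence")

    @model_validator(mode="after")
    def _therapy_mix(self) -> "CareBlock":
        total = self.p_oad.point_value + self.p_insulin.point_value + self.p_combo.point_value
        if total > 1.0:
            raise ValueError(f"p_oad + p_insulin + p_combo must be <= 1, got {total}")
        if set(self.provider_shares) != {"health_center", "cpa1", "cpa2", "cpa3"}:
            raise ValueError("provider_shares must have keys health_center, cpa1, cpa2, cpa3")
        for name, spec in self.provider_shares.items():
            if not 0 <= spec.point_value <= 1:
                raise ValueError(f"provider share {name} must be in [0, 1]")
        return self


class HefBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    eligibility_percentile: float = Field(gt=0, lt=1)
    enrollment: float = Field(ge=0, le=1)
    subsidy_rate: float = Field(ge=0, le=1)
    utilization: float = Field(ge=0, le=1)


class StrategyEffectsBlock(BaseModel):
    """Hypothesized behavioural effects of HEF coverage, applied to enrolled
    beneficiaries only (see ``hefsim.strategies``)."""

    model_config = ConfigDict(extra="forbid", frozen=True)
    rr_diagnosis: DistributionSpec
    rr_care_seeking: DistributionSpec
    rr_complication_care: DistributionSpec
    adherence_covered: DistributionSpec

    _v1 = _prob("adherence_covered")


class LifeExpectancyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    male: float = Field(gt=0)
    female: float = Field(gt=0)


class ParameterSet(BaseModel):
    """The full validated parameter registry."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    meta: dict[str, Any] = Field(default_factory=dict)
    costs: CostBlock
    transport: TransportBlock
    discount_rate: DistributionSpec
    population: PopulationBlock
    dw_uncomplicated: DistributionSpec
    dw_undiagnosed_counts: bool = True
    complications: list[ComplicationProfile]
    care: CareBlock
    hef: HefBlock
    strategy_effects: StrategyEffectsBlock
    life_expectancy: LifeExpectancyBlock
    poverty_line_daily: DistributionSpec
    horizon_years: int = Field(45, ge=1)
    national_population: int = Field(16_000_000, ge=1)

    @model_validator(mode="after")
    def _eight_complications(self) -> "ParameterSet":
        names = tuple(c.name for c in self.complications)
        if names != COMPLICATION_NAMES:
            raise ValueError(
                f"complications must be exactly {COMPLICATION_NAMES} in order, got {names}"
            )
        if not 0 <= self.dw_uncomplicated.point_value <= 1:
            raise ValueError("dw_uncomplicated must be in [0, 1]")
        return self

    def complication(self, name: str) -> ComplicationProfile:
        for c in self.complications:
            if c.name == name:
                return c
        raise KeyError(name)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.dump(), sort_keys=False))

    def dump(self) -> dict[str, Any]:
        return self.model_dump(mode="json")

    def replace(self, **updates: Any) -> "ParameterSet":
        """Return a copy with top-level blocks replaced (frozen model)."""
        data = self.model_dump()
        data.update(updates)
        return ParameterSet.model_validate(data)


def default_config_path() -> Path:
    return Path(str(importlib.resources.files("hefsim").joinpath("data/table2_base.yaml")))


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter registry from YAML.

    With no argument, loads the packaged base-case configuration. Unknown
    keys, out-of-range probabilities and negative costs are rejected with an
    error naming the offending parameter.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ParameterSet.model_validate(raw)


def iter_distribution_specs(params: ParameterSet) -> Iterator[tuple[str, DistributionSpec]]:
    """All named (possibly point) distribution specs in the registry."""
    for name, spec in params.costs.iter_specs():
        yield f"costs.{name}", spec
    yield "transport.outpatient", params.transport.outpatient
    yield "transport.inpatient", params.transport.inpatient
    yield "population.income", params.population.income
    for c in params.complications:
        yield f"complications.{c.name}.cost", c.cost
    care = params.care
    for f in ("p_diagnosis", "p_outpatient_non_hef", "p_outpatient_hef", "p_inpatient"):
        yield f"care.{f}", getattr(care, f)
    for level, spec in care.provider_shares.items():
        yield f"care.provider_shares.{level}", spec
    eff = params.strategy_effects
    for f in ("rr_diagnosis", "rr_care_seeking", "rr_complication_care"):
        yield f"strategy_effects.{f}", getattr(eff, f)


def consistency_report(params: ParameterSet, rel_tol: float = 0.05) -> list[str]:
    """Warnings where a sampling distribution's mean strays from its point value.

    The registry is transcribed verbatim from its sources, which contain a
    few internal inconsistencies (e.g. provider-share beta means well below
    the printed point shares, and an MI incidence an order of magnitude above
    the other cardiovascular incidences). This report surfaces them; it never
    raises.
    """
    warnings: list[str] = []
    for name, spec in iter_distribution_specs(params):
        if spec.family is Family.point:
            continue
        ref = spec.point_value
        mean = spec.mean()
        # per-day complication cost distributions live on the annual scale
        if name.startswith("complications."):
            comp = params.complication(name.split(".")[1])
            if comp.cost_unit == "per_day":
                ref = ref * 365.0
        if ref == 0:
            continue
        dev = abs(mean - ref) / abs(ref)
        if dev > rel_tol:
            warnings.append(
                f"{name}: distribution mean {mean:.4g} deviates {dev:.1%} "
                f"from point value {ref:.4g}"
            )
    mi = params.complication("mi")
    if mi.incidence > 0.05:
        warnings.append(
            f"complications.mi.incidence: {mi.incidence} is an order of magnitude above "
            "the other cardiovascular incidences (possible per-1000 transcription)"
        )
    return warnings
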