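"""HEF benefit-package strategies.

Seven strategies are modelled: the current standard (no effective financial
coverage for diabetes services) and six packages covering combinations of
diagnostics, drug therapy, and complication treatment. Coverage translates
into behaviour changes for *enrolled beneficiaries only*:

- diagnostics covered: care seeking RR 2.0 and diagnosis RR 1.5;
- drugs covered: adherence probability raised to 0.40 (replacing the 0.125
  baseline);
- complications covered: complication care seeking RR 2.0 (outpatient and
  inpatient).

Covered direct medical costs are split between the HEF (government) and the
patient at the configured subsidy rate; transport is always out-of-pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet, StrategyEffectsBlock

SEGMENTS = ("diagnostics", "drugs", "complications", "routine_visit")

_COMPONENTS = {
    "current_standard": (),
    "diagnostics_only": ("diagnostics",),
    "drug_therapy_only": ("drugs",),
    "complications_only": ("complications",),
    "diagnostics_drug": ("diagnostics", "drugs"),
    "drug_complications": ("drugs", "complications"),
    "diagnostics_drug_complications": ("diagnostics", "drugs", "complications"),
}

STRATEGY_NAMES = tuple(_COMPONENTS)


@dataclass(frozen=True)
class StrategySpec:
    """A benefit package: covered segments, effect modifiers, financing terms."""

    name: str
    covers_diagnostics: bool
    covers_drugs: bool
    covers_complications: bool
    rr_diagnosis: float
    rr_care_seeking: float
    adherence_override: float | None
    rr_complication_care: float
    eligibility_percentile: float
    subsidy_rate: float

    @property
    def is_null(self) -> bool:
        return not (self.covers_diagnostics or self.covers_drugs or self.covers_complications)


def build_strategy(
    name: str,
    eligibility_percentile: float = 0.20,
    subsidy_rate: float = 1.00,
    effects: StrategyEffectsBlock | None = None,
    params: ParameterSet | None = None,
) -> StrategySpec:
    """Construct one of the seven named strategies.

    Combined packages carry the union of their components' modifiers. Effect
    sizes default to the base-case point values; pass ``effects`` (e.g. a
    PSA draw) or ``params`` to override.
    """
    if name not in _COMPONENTS:
        raise ValueError(
            f"unknown strategy {name!r}; valid names: {', '.join(STRATEGY_NAMES)}"
        )
    if effects is None and params is not None:
        effects = params.strategy_effects
    if effects is not None:
        rr_dx = effects.rr_diagnosis.point_value
        rr_cs = effects.rr_care_seeking.point_value
        rr_cc = effects.rr_complication_care.point_value
        adh = effects.adherence_covered.point_value
    else:
        rr_dx, rr_cs, rr_cc, adh = 1.5, 2.0, 2.0, 0.40
    segs = _COMPONENTS[name]
    dx = "diagnostics" in segs
    drugs = "drugs" in segs
    comps = "complications" in segs
    return StrategySpec(
        name=name,
        covers_diagnostics=dx,
        covers_drugs=drugs,
        covers_complications=comps,
        rr_diagnosis=rr_dx if dx else 1.0,
        rr_care_seeking=rr_cs if dx else 1.0,
        adherence_override=adh if drugs else None,
        rr_complication_care=rr_cc if comps else 1.0,
        eligibility_percentile=eligibility_percentile,
        subsidy_rate=subsidy_rate,
    )


def with_effects(strategy: StrategySpec, effects: StrategyEffectsBlock) -> StrategySpec:
    """Re-derive a strategy's modifiers from (possibly PSA-drawn) effect sizes."""
    return build_strategy(
        strategy.name, strategy.eligibility_percentile, strategy.subsidy_rate, effects=effects
    )


def default_grid(
    eligibility: tuple[float, ...] = (0.20, 0.30),
    subsidy: tuple[float, ...] = (0.80, 1.00),
) -> list[StrategySpec]:
    """The full strategy x eligibility x subsidy comparison grid."""
    return [
        build_strategy(name, e, s)
        for name in STRATEGY_NAMES
        for e in eligibility
        for s in subsidy
    ]


def effective_probability(base: float, rr: float) -> float:
    """Apply a relative risk to a probability, capped at 1."""
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base must be a probability, got {base}")
    if rr < 0:
        raise ValueError(f"relative risk must be >= 0, got {rr}")
    return min(base * rr, 1.0)


def segment_covered(strategy: StrategySpec, segment: str) -> bool:
    if segment not in SEGMENTS:
        raise ValueError(f"unknown service segment {segment!r}")
    return {
        "diagnostics": strategy.covers_diagnostics,
        "drugs": strategy.covers_drugs,
        "complications": strategy.covers_complications,
        "routine_visit": False,
    }[segment]


def payer_split(
    direct_medical_cost: float,
    segment: str,
    enrolled: bool,
    strategy: StrategySpec,
) -> tuple[float, float]:
    """Split a direct medical cost into (government, out-of-pocket) shares.

    HEF pays ``subsidy_rate`` of covered segments for enrolled beneficiaries;
    everything else is out-of-pocket. Government + OOP always equals the
    cost. Transport costs never pass through here — they are always OOP.
    """
    if direct_medical_cost < 0:
        raise ValueError("cost must be >= 0")
    if enrolled and segment_covered(strategy, segment):
        gov = strategy.subsidy_rate * direct_medical_cost
        return gov, direct_medical_cost - gov
    return 0.0, direct_medical_cost
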