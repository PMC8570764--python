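"""Aggregate the person-year ledger into the evaluation's outcome measures.

Health impact is measured in DALYs = YLL + YLD, undiscounted. YLL counts
diabetes-attributable deaths only (diabetes-related and complication deaths;
background deaths are not premature mortality caused by the disease) and
values each at the remaining life expectancy at the age of death. YLD is
person-time times the combined disability weight.

Financial risk protection is measured per person-year against annual
household income: catastrophic health expenditure (CHE) when the year's
out-of-pocket spending (medical + transport, undiscounted) strictly exceeds
a threshold share of income, and impoverishment when OOP pushes a household
from above to below the international poverty line ($1.90/day).

Societal costs are discounted at 3%/yr; extensive totals are scaled to the
population the cohort represents. Incremental results versus the current
standard are summarized as ICERs with explicit dominance handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DEATH_COMPLICATION, DEATH_DIABETES, SimulationResult
from .parameters import ParameterSet

CHE_THRESHOLDS = (0.10, 0.25, 0.40)


@dataclass(frozen=True)
class OutcomeSummary:
    """Scaled totals for one strategy run."""

    strategy_name: str
    eligibility: float
    subsidy: float
    scale_factor: float
    total_cost: float  # discounted, scaled
    cost_government: float
    cost_oop: float  # medical + transport
    dalys: float  # undiscounted, scaled
    yll: float
    yld: float
    che_cases: dict[float, float]
    impoverishment_cases: float
    oop_undiscounted: float
    dalys_by_sex: dict[str, float]
    che_by_sex: dict[str, float]
    n_ever_diabetic: float  # scaled
    diabetic_person_years: float  # scaled


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention minus comparator, with ICERs."""

    comparator: OutcomeSummary
    intervention: OutcomeSummary
    delta_cost: float
    delta_dalys: float  # negative = averted
    delta_che: float  # at the 40% threshold; negative = averted
    icer_daly: float | None
    icer_daly_status: str
    icer_che: float | None
    icer_che_status: str


def discounted_cost(amount: float, year: int, rate: float) -> float:
    """Present value of ``amount`` accrued in cycle ``year`` (year 0 undiscounted)."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if year < 0:
        raise ValueError("year must be >= 0")
    if rate <= -1:
        raise ValueError("rate must be > -1")
    return amount / (1.0 + rate) ** year


def _discount_factors(years: np.ndarray, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + rate) ** years.astype(float)


def remaining_life_expectancy(age: np.ndarray, sex: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Remaining life expectancy at a given age: max(0, LE_at_birth - age)."""
    le0 = np.where(
        np.asarray(sex) == 0, params.life_expectancy.male, params.life_expectancy.female
    )
    return np.maximum(0.0, le0 - np.asarray(age, dtype=float))


def compute_dalys(result: SimulationResult, params: ParameterSet) -> tuple[float, float]:
    """(YLL, YLD), unscaled and undiscounted.

    YLL sums remaining life expectancy at death over diabetes-attributable
    deaths (diabetes-related and complication case fatality). YLD sums the
    ledger's per-person-year disability.
    """
    persons = result.persons
    attributable = persons["death_cause"].isin([DEATH_DIABETES, DEATH_COMPLICATION]).to_numpy()
    yll = float(
        remaining_life_expectancy(
            persons.loc[attributable, "age_at_death"].to_numpy(),
            persons.loc[attributable, "sex"].to_numpy(),
            params,
        ).sum()
    )
    yld = float(result.ledger["yld"].sum())
    return yll, yld


def _oop_by_person_year(result: SimulationResult) -> pd.DataFrame:
    led = result.ledger
    df = pd.DataFrame(
        {
            "person_id": led["person_id"],
            "diabetic": led["disease_state"].to_numpy() > 0,
            "oop": led["cost_oop_medical"].to_numpy() + led["cost_oop_transport"].to_numpy(),
        }
    )
    people = result.persons.set_index("id")
    df["income"] = people["income"].reindex(df["person_id"].to_numpy()).to_numpy()
    df["sex"] = people["sex"].reindex(df["person_id"].to_numpy()).to_numpy()
    return df


def che_cases(result: SimulationResult, threshold: float) -> int:
    """Unscaled diabetic person-years with annual OOP strictly above
    ``threshold`` x annual household income."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    df = _oop_by_person_year(result)
    return int((df["diabetic"] & (df["oop"] > threshold * df["income"])).sum())


def impoverishment_cases(result: SimulationResult, params: ParameterSet) -> int:
    """Unscaled person-years pushed below the poverty line by OOP spending."""
    line = params.poverty_line_daily.point_value * 365.0
    df = _oop_by_person_year(result)
    return int(((df["income"] >= line) & (df["income"] - df["oop"] < line)).sum())


def icer(delta_cost: float, delta_effect: float) -> tuple[float | None, str]:
    """ICER with dominance handling.

    ``delta_effect`` is the quantity *averted* (positive = intervention is
    better). Returns ``(ratio, status)``: the raw signed ratio (rounded for
    reporting by callers) with status "ok" for a positive trade-off,
    "dominant" when the intervention saves money and averts harm, and
    "dominated" (ratio None) when it costs more and averts nothing.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("inputs must be finite")
    if delta_effect > 0:
        ratio = delta_cost / delta_effect
        return ratio, ("dominant" if delta_cost <= 0 else "ok")
    if delta_cost <= 0 and delta_effect == 0:
        return None, "dominant"
    return None, "dominated"


def summarize(result: SimulationResult, params: ParameterSet) -> OutcomeSummary:
    """Scale a run's ledger into an :class:`OutcomeSummary`."""
    led = result.ledger
    scale = result.cohort.scale_factor
    rate = params.discount_rate.point_value
    disc = _discount_factors(led["year"].to_numpy(), rate)
    gov = float((led["cost_government"].to_numpy() * disc).sum())
    oop_arr = led["cost_oop_medical"].to_numpy() + led["cost_oop_transport"].to_numpy()
    oop = float((oop_arr * disc).sum())
    yll, yld = compute_dalys(result, params)

    df = _oop_by_person_year(result)
    che = {t: che_cases(result, t) for t in CHE_THRESHOLDS}
    imp = impoverishment_cases(result, params)

    # per-sex breakdowns
    persons = result.persons
    attributable = persons["death_cause"].isin([DEATH_DIABETES, DEATH_COMPLICATION])
    dalys_by_sex = {}
    che_by_sex = {}
    led_sex = df["sex"].to_numpy()
    che40 = df["diabetic"] & (df["oop"] > 0.40 * df["income"])
    for code, label in ((0, "male"), (1, "female")):
        sel = attributable & (persons["sex"] == code)
        yll_s = float(
            remaining_life_expectancy(
                persons.loc[sel, "age_at_death"].to_numpy(),
                persons.loc[sel, "sex"].to_numpy(),
                params,
            ).sum()
        )
        yld_s = float(led.loc[led_sex == code, "yld"].sum())
        dalys_by_sex[label] = (yll_s + yld_s) * scale
        che_by_sex[label] = float(che40[led_sex == code].sum()) * scale

    return OutcomeSummary(
        strategy_name=result.strategy.name,
        eligibility=result.strategy.eligibility_percentile,
        subsidy=result.strategy.subsidy_rate,
        scale_factor=scale,
        total_cost=(gov + oop) * scale,
        cost_government=gov * scale,
        cost_oop=oop * scale,
        dalys=(yll + yld) * scale,
        yll=yll * scale,
        yld=yld * scale,
        che_cases={t: c * scale for t, c in che.items()},
        impoverishment_cases=imp * scale,
        oop_undiscounted=float(oop_arr.sum()) * scale,
        dalys_by_sex=dalys_by_sex,
        che_by_sex=che_by_sex,
        n_ever_diabetic=float(persons["ever_diabetic"].sum()) * scale,
        diabetic_person_years=float((led["disease_state"].to_numpy() > 0).sum()) * scale,
    )


def incremental(comparator: OutcomeSummary, intervention: OutcomeSummary) -> IncrementalResult:
    """Incremental comparison against the current standard."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_dalys = intervention.dalys - comparator.dalys
    d_che = intervention.che_cases[0.40] - comparator.che_cases[0.40]
    icer_daly, st_daly = icer(d_cost, -d_dalys)
    icer_che, st_che = icer(d_cost, -d_che)
    return IncrementalResult(
        comparator=comparator,
        intervention=intervention,
        delta_cost=d_cost,
        delta_dalys=d_dalys,
        delta_che=d_che,
        icer_daly=icer_daly,
        icer_daly_status=st_daly,
        icer_che=icer_che,
        icer_che_status=st_che,
    )


def scale_results(summary: OutcomeSummary, scale_factor: float) -> OutcomeSummary:
    """Multiply all extensive quantities by ``scale_factor`` (ratios unchanged)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    s = scale_factor
    return OutcomeSummary(
        strategy_name=summary.strategy_name,
        eligibility=summary.eligibility,
        subsidy=summary.subsidy,
        scale_factor=summary.scale_factor * s,
        total_cost=summary.total_cost * s,
        cost_government=summary.cost_government * s,
        cost_oop=summary.cost_oop * s,
        dalys=summary.dalys * s,
        yll=summary.yll * s,
        yld=summary.yld * s,
        che_cases={t: c * s for t, c in summary.che_cases.items()},
        impoverishment_cases=summary.impoverishment_cases * s,
        oop_undiscounted=summary.oop_undiscounted * s,
        dalys_by_sex={k: v * s for k, v in summary.dalys_by_sex.items()},
        che_by_sex={k: v * s for k, v in summary.che_by_sex.items()},
        n_ever_diabetic=summary.n_ever_diabetic * s,
        diabetic_person_years=summary.diabetic_person_years * s,
    )


def daly_table(results: list[IncrementalResult]) -> pd.DataFrame:
    """Comparison table: costs, DALYs, incrementals and cost per DALY averted."""
    rows = []
    for r in results:
        icer_txt = "" if r.icer_daly is None else round(r.icer_daly)
        rows.append(
            {
                "strategy": r.intervention.strategy_name,
                "eligibility": r.intervention.eligibility,
                "total_cost": round(r.intervention.total_cost),
                "incremental_cost": round(r.delta_cost),
                "dalys": round(r.intervention.dalys),
                "incremental_dalys": round(r.delta_dalys),
                "icer_per_daly_averted": icer_txt,
                "icer_status": r.icer_daly_status,
            }
        )
    return pd.DataFrame(rows)


def che_table(results: list[IncrementalResult]) -> pd.DataFrame:
    """Comparison table: costs, CHE cases (40% threshold), incrementals, ICERs."""
    rows = []
    for r in results:
        icer_txt = "" if r.icer_che is None else round(r.icer_che)
        rows.append(
            {
                "strategy": r.intervention.strategy_name,
                "eligibility": r.intervention.eligibility,
                "oop_coverage": r.intervention.subsidy,
                "total_cost": round(r.intervention.total_cost),
                "incremental_cost": round(r.delta_cost),
                "che_cases": round(r.intervention.che_cases[0.40]),
                "incremental_che": round(r.delta_che),
                "icer_per_che_averted": icer_txt,
                "icer_status": r.icer_che_status,
            }
        )
    return pd.DataFrame(rows)
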