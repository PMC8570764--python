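"""Two-layer uncertainty analysis: parameter draws and population bootstrap.

Layer one draws parameter sets from the registry's distributions: costs
lognormal, care probabilities beta, strategy relative risks normal with
variance 0.1 truncated at zero; parameters without a distribution stay at
their point values. Layer two resamples the cohort with replacement.

Each (population, parameter set) cell runs every strategy against the
current standard with common random numbers, producing a distribution of
incremental costs, DALYs and CHE cases per strategy, summarized by 2.5th and
97.5th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import simulate
from .outcomes import incremental, summarize
from .parameters import Family, ParameterSet, iter_distribution_specs, sample_parameter
from .population import Cohort, bootstrap_cohort
from .strategies import StrategySpec, with_effects


@dataclass(frozen=True)
class PSADesign:
    n_parameter_sets: int = 50
    rr_variance: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_parameter_sets < 1:
            raise ValueError("n_parameter_sets must be >= 1")


@dataclass(frozen=True)
class BootstrapDesign:
    n_populations: int = 100
    sample_size: int = 40_000
    seed: int = 0

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")


def _set_by_path(data: dict, path: str, value: float) -> None:
    keys = path.split(".")
    node = data
    for k in keys[:-1]:
        node = node[k]
    node[keys[-1]]["point_value"] = value


def draw_psa_set(params: ParameterSet, rng: np.random.Generator, rr_variance: float) -> ParameterSet:
    """One parameter set with point values replaced by distribution draws."""
    data = params.model_dump()
    for name, spec in iter_distribution_specs(params):
        if spec.family is Family.point:
            continue
        if name == "population.income":
            continue  # the income model defines the population, not a sampled input
        if name.startswith("strategy_effects."):
            drawn = max(0.0, float(rng.normal(spec.p1, np.sqrt(rr_variance))))
        else:
            drawn = sample_parameter(spec, rng)
        if name.startswith("complications."):
            comp_name = name.split(".")[1]
            comp = params.complication(comp_name)
            if comp.cost_unit == "per_day":
                drawn /= 365.0  # distribution is on the annualized scale
            for c in data["complications"]:
                if c["name"] == comp_name:
                    c["cost"]["point_value"] = drawn
            continue
        if name.startswith("care.") and drawn > 1.0:
            drawn = 1.0
        _set_by_path(data, name, drawn)
    return ParameterSet.model_validate(data)


def draw_psa_sets(params: ParameterSet, design: PSADesign) -> list[ParameterSet]:
    """``n_parameter_sets`` independent draws; child streams are spawned per
    set, so extending the design leaves earlier draws unchanged."""
    children = np.random.SeedSequence(design.seed).spawn(design.n_parameter_sets)
    return [
        draw_psa_set(params, np.random.default_rng(ss), design.rr_variance) for ss in children
    ]


def run_uncertainty(
    cohort: Cohort,
    strategies: list[StrategySpec],
    params: ParameterSet,
    psa: PSADesign,
    boot: BootstrapDesign,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Full cross of bootstrap populations x parameter sets.

    Returns a long-format frame with one row per (strategy, population,
    parameter set): incremental cost, DALYs and CHE cases (40% threshold)
    versus the current standard run on the same population with the same
    random stream.
    """
    param_sets = draw_psa_sets(params, psa)
    pop_rng = np.random.default_rng(np.random.SeedSequence([boot.seed, 0xB007]))
    run_seeds = np.random.SeedSequence([boot.seed, psa.seed, 0x5EED]).generate_state(
        boot.n_populations * psa.n_parameter_sets
    ) % (2**31)

    rows = []
    cell = 0
    for pop_id in range(boot.n_populations):
        pop = bootstrap_cohort(cohort, boot.sample_size, pop_rng)
        for set_id, pset in enumerate(param_sets):
            seed = int(run_seeds[cell])
            cell += 1
            base = simulate(pop, _current_standard(strategies, pset), pset, seed, horizon)
            base_sum = summarize(base, pset)
            for strat in strategies:
                if strat.name == "current_standard":
                    continue
                strat_drawn = with_effects(strat, pset.strategy_effects)
                res = simulate(pop, strat_drawn, pset, seed, horizon)
                inc = incremental(base_sum, summarize(res, pset))
                rows.append(
                    {
                        "strategy": strat.name,
                        "population_id": pop_id,
                        "param_set_id": set_id,
                        "delta_cost": inc.delta_cost,
                        "delta_dalys": inc.delta_dalys,
                        "delta_che": inc.delta_che,
                    }
                )
    return pd.DataFrame(rows)


def _current_standard(strategies: list[StrategySpec], params: ParameterSet) -> StrategySpec:
    for s in strategies:
        if s.name == "current_standard":
            return s
    from .strategies import build_strategy

    return build_strategy("current_standard", params.hef.eligibility_percentile,
                          params.hef.subsidy_rate)


def summarize_uncertainty(long: pd.DataFrame) -> pd.DataFrame:
    """95% uncertainty ranges per strategy plus the share of runs in which no
    DALYs were averted."""
    out = []
    for name, grp in long.groupby("strategy", sort=False):
        row = {"strategy": name, "n_runs": len(grp)}
        for col in ("delta_cost", "delta_dalys", "delta_che"):
            row[f"{col}_p2.5"] = float(np.percentile(grp[col], 2.5))
            row[f"{col}_p50"] = float(np.percentile(grp[col], 50))
            row[f"{col}_p97.5"] = float(np.percentile(grp[col], 97.5))
        row["frac_no_dalys_averted"] = float((grp["delta_dalys"] >= 0).mean())
        out.append(row)
    return pd.DataFrame(out)
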