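"""Annual-cycle Markov microsimulation of diabetes and its care pathway.

Each of the 45 annual cycles applies, in fixed order:

1. background all-cause mortality (age/sex schedule);
2. diabetes onset among non-diabetics;
3. care seeking and screening/diagnosis of undiagnosed diabetics;
4. therapy assignment for the newly diagnosed, OAD-to-insulin switching,
   and the yearly adherence draw;
5. complication incidence, modified by glucose control (therapy RR when
   adherent, diet RR 0.90 when diagnosed-untreated);
6. care seeking and treatment costs for active complications;
7. complication case fatality (acute in the event year; chronic annually)
   and diabetes-related mortality among diabetics not adherent on therapy;
8. disability (YLD) accrual.

The engine is vectorized across the cohort. Every cycle draws fixed-shape
uniform arrays for the whole cohort regardless of who is alive or at risk,
so two strategies run with the same seed consume identical random streams
("common random numbers"): any divergence in outcomes is attributable to the
strategies, not Monte-Carlo noise. Treatment of complications does not
affect complication mortality (no curative-effect pathway is modelled).

Costs are recorded undiscounted, by payer, one row per person-year lived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .population import (
    Cohort,
    DIAGNOSED_UNTREATED,
    NO_DIABETES,
    ON_COMBO,
    ON_INSULIN,
    ON_OAD,
    UNDIAGNOSED,
)
from .strategies import StrategySpec, effective_probability, payer_split

# death causes
DEATH_NONE = 0
DEATH_BACKGROUND = 1
DEATH_DIABETES = 2
DEATH_COMPLICATION = 3

LEVELS = ("health_center", "cpa1", "cpa2", "cpa3")

LEDGER_COLUMNS = [
    "person_id",
    "year",
    "disease_state",
    "comp_mask",
    "new_comp_mask",
    "event_onset",
    "event_diagnosis",
    "adherent",
    "cost_government",
    "cost_oop_medical",
    "cost_oop_transport",
    "yld",
    "death_cause",
]


@dataclass(frozen=True)
class SimulationResult:
    """Person-year ledger plus per-person end states for one strategy run."""

    ledger: pd.DataFrame
    persons: pd.DataFrame  # id, sex, income, enrolled, age0, age_at_death, death_cause, ever_diabetic
    cohort: Cohort
    strategy: StrategySpec
    seed: int
    horizon: int

    def ledger_csv(self, path) -> None:
        self.ledger.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        led = self.ledger
        return {
            "strategy": self.strategy.name,
            "seed": self.seed,
            "horizon": self.horizon,
            "n_persons": len(self.persons),
            "person_years": int(len(led)),
            "diabetic_person_years": int((led["disease_state"].to_numpy() > 0).sum()),
            "deaths": int((self.persons["death_cause"] > 0).sum()),
            "total_cost_government": float(led["cost_government"].sum()),
            "total_cost_oop_medical": float(led["cost_oop_medical"].sum()),
            "total_cost_oop_transport": float(led["cost_oop_transport"].sum()),
            "total_yld": float(led["yld"].sum()),
        }


class _Params:
    """Point values unpacked into plain arrays for the hot loop."""

    def __init__(self, p: ParameterSet):
        care = p.care
        self.p_onset = p.population.diabetes_incidence.point_value
        self.p_dm_mort = p.population.diabetes_mortality.point_value
        self.p_dx = care.p_diagnosis.point_value
        self.p_out_nonhef = care.p_outpatient_non_hef.point_value
        self.p_out_hef = care.p_outpatient_hef.point_value
        self.p_inpatient = care.p_inpatient.point_value
        self.p_oad = care.p_oad.point_value
        self.p_insulin = care.p_insulin.point_value
        self.p_combo = care.p_combo.point_value
        self.p_switch = care.p_oad_to_insulin.point_value
        self.p_adherence = care.p_adherence.point_value
        self.rr_diet = care.rr_diet.point_value
        self.los = care.los_days.point_value
        shares = np.array([care.provider_shares[l].point_value for l in LEVELS])
        self.provider_cum = np.cumsum(shares / shares.sum())  # conditional on a public visit
        self.out_cost = np.array([p.costs.outpatient_visit[l].point_value for l in LEVELS])
        self.inp_cost_day = np.array([p.costs.inpatient_per_day[l].point_value for l in LEVELS])
        self.c_fpg = p.costs.diagnostics.point_value
        self.c_lab = p.costs.laboratory.point_value
        self.c_oad = p.costs.oad_annual.point_value
        self.c_insulin = p.costs.insulin_annual.point_value
        self.tr_out = p.transport.outpatient.point_value
        self.tr_in = p.transport.inpatient.point_value
        self.dw_base = p.dw_uncomplicated.point_value
        self.dw_undiag = p.dw_undiagnosed_counts
        comps = p.complications
        self.n_comp = len(comps)
        self.comp_names = [c.name for c in comps]
        self.inc = np.array([c.incidence for c in comps])
        self.rr_therapy = np.array([c.rr_therapy for c in comps])
        self.dw = np.array([c.disability_weight for c in comps])
        self.cf = np.array([c.case_fatality for c in comps])
        self.acute = np.array([c.acute for c in comps])
        self.inpatient_setting = np.array([c.cost_setting == "inpatient" for c in comps])
        # annual outpatient therapy cost / per-day inpatient drug cost
        self.comp_cost_annual = np.array(
            [c.cost.point_value * (365.0 if c.cost_unit == "per_day" else 1.0) for c in comps]
        )
        self.comp_cost_daily = np.array(
            [c.cost.point_value if c.cost_unit == "per_day" else c.cost.point_value / 365.0 for c in comps]
        )
        # background mortality schedule lookup
        bands = p.population.mortality_schedule
        self.band_edges = np.array([b.age_lo for b in bands] + [bands[-1].age_hi])
        self.band_q = np.array([[b.male, b.female] for b in bands])  # (n_bands, 2)

    def background_hazard(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.band_edges, age, side="right") - 1, 0, len(self.band_q) - 1)
        return self.band_q[idx, sex]


def simulate(
    cohort: Cohort,
    strategy: StrategySpec,
    params: ParameterSet,
    seed: int,
    horizon: int | None = None,
) -> SimulationResult:
    """Run the microsimulation for one strategy.

    Deterministic given ``seed``; identical seeds across strategies give
    common random numbers. Raises on an empty cohort.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    horizon = params.horizon_years if horizon is None else horizon
    pp = _Params(params)
    rng = np.random.default_rng(seed)

    persons = cohort.persons
    sex = persons["sex"].to_numpy().astype(np.intp)
    age = persons["age"].to_numpy().astype(np.float64).copy()
    income = persons["income"].to_numpy().astype(np.float64)
    enrolled = persons["hef_enrolled"].to_numpy().astype(bool)
    state = persons["disease_state"].to_numpy().astype(np.int8).copy()

    alive = np.ones(n, dtype=bool)
    comp_active = np.zeros((n, pp.n_comp), dtype=bool)
    age_at_death = np.full(n, np.nan)
    death_cause = np.zeros(n, dtype=np.int8)
    ever_diabetic = state > NO_DIABETES

    # enrolled-beneficiary effective probabilities under this strategy
    p_visit_hef = effective_probability(pp.p_out_hef, strategy.rr_care_seeking)
    p_dx_hef = effective_probability(pp.p_dx, strategy.rr_diagnosis)
    p_out_care_hef = effective_probability(pp.p_out_hef, strategy.rr_complication_care)
    p_inp_care_hef = effective_probability(pp.p_inpatient, strategy.rr_complication_care)
    p_adh_hef = (
        strategy.adherence_override if strategy.adherence_override is not None else pp.p_adherence
    )

    rows: list[dict[str, np.ndarray]] = []

    for year in range(horizon):
        # fixed-shape draws -> common random numbers across strategies
        u_bg = rng.random(n)
        u_onset = rng.random(n)
        u_visit = rng.random(n)
        u_prov = rng.random(n)
        u_dx = rng.random(n)
        u_assign = rng.random(n)
        u_switch = rng.random(n)
        u_adh = rng.random(n)
        u_inc = rng.random((n, pp.n_comp))
        u_care = rng.random((n, pp.n_comp))
        u_prov_inp = rng.random(n)
        u_cf = rng.random((n, pp.n_comp))
        u_dm = rng.random(n)

        at_start = alive.copy()
        if not at_start.any():
            break

        cost_gov = np.zeros(n)
        cost_oop_med = np.zeros(n)
        cost_oop_tr = np.zeros(n)
        event_onset = np.zeros(n, dtype=bool)
        event_dx = np.zeros(n, dtype=bool)
        new_comp = np.zeros((n, pp.n_comp), dtype=bool)

        # 1. background mortality
        died_bg = alive & (u_bg < pp.background_hazard(age, sex))
        alive &= ~died_bg
        age_at_death[died_bg] = age[died_bg]
        death_cause[died_bg] = DEATH_BACKGROUND

        # 2. diabetes onset
        onset = alive & (state == NO_DIABETES) & (u_onset < pp.p_onset)
        state[onset] = UNDIAGNOSED
        ever_diabetic |= onset
        event_onset = onset

        # 3. care seeking + screening/diagnosis of the undiagnosed
        undiag = alive & (state == UNDIAGNOSED)
        p_visit = np.where(enrolled, p_visit_hef if strategy.covers_diagnostics else pp.p_out_hef,
                           pp.p_out_nonhef)
        visit = undiag & (u_visit < p_visit)
        level = np.searchsorted(pp.provider_cum, u_prov)
        visit_med = pp.out_cost[level] + pp.c_fpg + pp.c_lab
        gov_share = np.where(
            enrolled & strategy.covers_diagnostics, strategy.subsidy_rate, 0.0
        )
        cost_gov += np.where(visit, gov_share * visit_med, 0.0)
        cost_oop_med += np.where(visit, (1.0 - gov_share) * visit_med, 0.0)
        cost_oop_tr += np.where(visit, pp.tr_out, 0.0)
        p_dx_eff = np.where(enrolled & strategy.covers_diagnostics, p_dx_hef, pp.p_dx)
        event_dx = visit & (u_dx < p_dx_eff)
        state[event_dx] = DIAGNOSED_UNTREATED

        # 4. therapy assignment, switching, adherence, drug costs
        on_oad_before = alive & (state == ON_OAD) & ~event_dx
        assign_oad = event_dx & (u_assign < pp.p_oad)
        assign_ins = event_dx & (u_assign >= pp.p_oad) & (u_assign < pp.p_oad + pp.p_insulin)
        assign_com = event_dx & (u_assign >= pp.p_oad + pp.p_insulin) & (
            u_assign < pp.p_oad + pp.p_insulin + pp.p_combo
        )
        state[assign_oad] = ON_OAD
        state[assign_ins] = ON_INSULIN
        state[assign_com] = ON_COMBO
        switch = on_oad_before & (u_switch < pp.p_switch)
        state[switch] = ON_INSULIN

        treated = alive & (state >= ON_OAD)
        p_adh = np.where(enrolled & strategy.covers_drugs, p_adh_hef, pp.p_adherence)
        adherent = treated & (u_adh < p_adh)
        # prescribed therapy is dispensed (and costed) every treated person-year;
        # the adherence draw governs effectiveness, not billing
        drug_cost = np.zeros(n)
        drug_cost[treated & (state == ON_OAD)] = pp.c_oad
        drug_cost[treated & (state == ON_INSULIN)] = pp.c_insulin
        drug_cost[treated & (state == ON_COMBO)] = pp.c_oad + pp.c_insulin
        gov_share = np.where(enrolled & strategy.covers_drugs, strategy.subsidy_rate, 0.0)
        cost_gov += gov_share * drug_cost
        cost_oop_med += (1.0 - gov_share) * drug_cost

        # 5. complication incidence, modified by glucose control
        diabetic = alive & (state > NO_DIABETES)
        mod = np.ones(n)
        mod[alive & (state == DIAGNOSED_UNTREATED)] = pp.rr_diet
        hazard = pp.inc[None, :] * np.where(adherent[:, None], pp.rr_therapy[None, :], mod[:, None])
        new_comp = diabetic[:, None] & ~comp_active & (u_inc < hazard)
        comp_active |= new_comp

        # 6. complication care and costs
        p_out_care = np.where(
            enrolled,
            p_out_care_hef if strategy.covers_complications else pp.p_out_hef,
            pp.p_out_nonhef,
        )
        p_inp_care = np.where(
            enrolled & strategy.covers_complications, p_inp_care_hef, pp.p_inpatient
        )
        p_care = np.where(pp.inpatient_setting[None, :], p_inp_care[:, None], p_out_care[:, None])
        cared = comp_active & alive[:, None] & (u_care < p_care)
        inp_level = np.searchsorted(pp.provider_cum, u_prov_inp)
        # outpatient therapy: annualized drug/treatment cost; inpatient episode:
        # facility hotel cost + complication drug cost, both per day x LOS
        episode_med = np.where(
            pp.inpatient_setting[None, :],
            (pp.inp_cost_day[inp_level][:, None] + pp.comp_cost_daily[None, :]) * pp.los,
            pp.comp_cost_annual[None, :],
        )
        episode_tr = np.where(pp.inpatient_setting[None, :], pp.tr_in, pp.tr_out)
        gov_share = np.where(enrolled & strategy.covers_complications, strategy.subsidy_rate, 0.0)
        med_total = (cared * episode_med).sum(axis=1)
        cost_gov += gov_share * med_total
        cost_oop_med += (1.0 - gov_share) * med_total
        cost_oop_tr += (cared * episode_tr).sum(axis=1)

        # 7. complication and diabetes-related mortality
        at_risk = new_comp & pp.acute[None, :] | (comp_active & ~pp.acute[None, :])
        comp_death = (at_risk & (u_cf < pp.cf[None, :])).any(axis=1) & alive
        unprotected = diabetic & ~adherent
        dm_death = unprotected & (u_dm < pp.p_dm_mort) & ~comp_death
        died_now = comp_death | dm_death
        age_at_death[died_now] = age[died_now]
        death_cause[comp_death] = DEATH_COMPLICATION
        death_cause[dm_death] = DEATH_DIABETES
        alive &= ~died_now

        # 8. disability accrual for everyone who lived through the year
        lived = at_start & ~died_bg
        dw_basis = np.where(
            (state >= DIAGNOSED_UNTREATED) | ((state == UNDIAGNOSED) & pp.dw_undiag),
            pp.dw_base,
            0.0,
        )
        healthy_frac = (1.0 - dw_basis) * np.prod(
            np.where(comp_active, 1.0 - pp.dw[None, :], 1.0), axis=1
        )
        yld = np.where(lived, 1.0 - healthy_frac, 0.0)

        idx = np.flatnonzero(at_start)
        comp_mask = (comp_active[idx] @ (1 << np.arange(pp.n_comp))).astype(np.int16)
        new_mask = (new_comp[idx] @ (1 << np.arange(pp.n_comp))).astype(np.int16)
        rows.append(
            {
                "person_id": idx.astype(np.int64),
                "year": np.full(idx.size, year, dtype=np.int16),
                "disease_state": state[idx].copy(),
                "comp_mask": comp_mask,
                "new_comp_mask": new_mask,
                "event_onset": event_onset[idx],
                "event_diagnosis": event_dx[idx],
                "adherent": adherent[idx],
                "cost_government": cost_gov[idx],
                "cost_oop_medical": cost_oop_med[idx],
                "cost_oop_transport": cost_oop_tr[idx],
                "yld": yld[idx],
                "death_cause": np.where(
                    died_bg[idx] | comp_death[idx] | dm_death[idx], death_cause[idx], DEATH_NONE
                ).astype(np.int8),
            }
        )
        age[alive] += 1.0

    ledger = pd.DataFrame(
        {col: np.concatenate([r[col] for r in rows]) for col in LEDGER_COLUMNS}
    )
    person_df = pd.DataFrame(
        {
            "id": persons["id"].to_numpy(),
            "sex": sex,
            "income": income,
            "hef_enrolled": enrolled,
            "age0": persons["age"].to_numpy(),
            "age_at_death": age_at_death,
            "death_cause": death_cause,
            "ever_diabetic": ever_diabetic,
        }
    )
    return SimulationResult(
        ledger=ledger,
        persons=person_df,
        cohort=cohort,
        strategy=strategy,
        seed=seed,
        horizon=horizon,
    )
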