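"""Outcome aggregation: DALYs, discounting, CHE, impoverishment, ICERs."""

import numpy as np
import pandas as pd
import pytest

from hefsim import (
    build_strategy,
    che_cases,
    compute_dalys,
    discounted_cost,
    generate_eligible_cohort,
    icer,
    impoverishment_cases,
    incremental,
    scale_results,
    simulate,
    summarize,
)
from hefsim.engine import DEATH_DIABETES, SimulationResult
from hefsim.outcomes import remaining_life_expectancy

from conftest import make_cohort, mutate, zero_mortality


def _result_with_ledger(params, ledger_rows, persons_rows, strategy=None):
    """Assemble a SimulationResult from hand-written person-year rows."""
    defaults = dict(
        disease_state=1, comp_mask=0, new_comp_mask=0, event_onset=False,
        event_diagnosis=False, adherent=False, cost_government=0.0,
        cost_oop_medical=0.0, cost_oop_transport=0.0, yld=0.0, death_cause=0,
    )
    led = pd.DataFrame([{**defaults, **r} for r in ledger_rows])
    pdefaults = dict(sex=0, income=1000.0, hef_enrolled=False, age0=40.0,
                     age_at_death=np.nan, death_cause=0, ever_diabetic=True)
    per = pd.DataFrame([{**pdefaults, **r} for r in persons_rows])
    strategy = strategy or build_strategy("current_standard", 0.20, 1.00)
    cohort_df = per.rename(columns={"age0": "age"})[["id", "sex", "age", "income"]].copy()
    cohort_df["hef_eligible"] = True
    cohort_df["hef_enrolled"] = per["hef_enrolled"]
    cohort_df["disease_state"] = 1
    from hefsim.population import Cohort

    cohort = Cohort(persons=cohort_df, scale_factor=1.0, seed=0)
    return SimulationResult(ledger=led, persons=per, cohort=cohort,
                            strategy=strategy, seed=0, horizon=45)


class TestDalys:
    def test_yll_zero_at_life_expectancy_exhaustion(self, params):
        age = np.array([67.0]); sex = np.array([0])
        assert remaining_life_expectancy(age, sex, params)[0] == 0.0
        assert remaining_life_expectancy(np.array([61.0]), np.array([1]), params)[0] == 10.0

    def test_single_disability_year(self, params):
        res = _result_with_ledger(params, [{"person_id": 0, "year": 0, "yld": 0.049}],
                                  [{"id": 0}])
        yll, yld = compute_dalys(res, params)
        assert (yll, yld) == (0.0, pytest.approx(0.049))

    def test_comorbid_disability_combines_multiplicatively(self, params):
        """Diabetes (0.049) + stroke sequela (0.588) -> 0.608 in one person-year."""
        p = zero_mortality(params)
        data = p.model_dump()
        for comp in data["complications"]:
            comp["incidence"] = 1.0 if comp["name"] == "stroke" else 0.0
        from hefsim import ParameterSet
        p = ParameterSet.model_validate(data)
        from hefsim.population import DIAGNOSED_UNTREATED
        coh = make_cohort(1, disease_state=DIAGNOSED_UNTREATED)
        res = simulate(coh, build_strategy("current_standard", 0.20, 1.00), p, seed=1, horizon=1)
        assert res.ledger["yld"].iloc[0] == pytest.approx(1 - (1 - 0.049) * (1 - 0.588))

    def test_yll_counts_diabetes_attributable_deaths(self, params):
        res = _result_with_ledger(
            params,
            [{"person_id": 0, "year": 0, "death_cause": DEATH_DIABETES}],
            [{"id": 0, "sex": 0, "age_at_death": 47.0, "death_cause": DEATH_DIABETES}],
        )
        yll, _ = compute_dalys(res, params)
        assert yll == pytest.approx(20.0)  # male LE 67 - 47

    def test_background_death_contributes_no_yll(self, params):
        res = _result_with_ledger(
            params,
            [{"person_id": 0, "year": 0, "death_cause": 1}],
            [{"id": 0, "age_at_death": 40.0, "death_cause": 1}],
        )
        assert compute_dalys(res, params)[0] == 0.0

    def test_daly_additivity_over_cohort_partition(self, params):
        coh = generate_eligible_cohort(params, 3000, seed=21)
        strat = build_strategy("current_standard", 0.20, 1.00, params=params)
        res = simulate(coh, strat, params, seed=21)
        ids = res.persons["id"].to_numpy()
        half = set(ids[: len(ids) // 2])

        def sub(result, keep):
            mask_l = result.ledger["person_id"].isin(keep)
            mask_p = result.persons["id"].isin(keep)
            return SimulationResult(
                ledger=result.ledger[mask_l], persons=result.persons[mask_p],
                cohort=result.cohort, strategy=result.strategy,
                seed=result.seed, horizon=result.horizon,
            )

        a = compute_dalys(sub(res, half), params)
        b = compute_dalys(sub(res, set(ids) - half), params)
        whole = compute_dalys(res, params)
        assert a[0] + b[0] == pytest.approx(whole[0])
        assert a[1] + b[1] == pytest.approx(whole[1])


class TestDiscounting:
    @pytest.mark.parametrize(
        "amount,year,rate,expected",
        [(100, 0, 0.03, 100.0), (100, 2, 0.03, 94.26), (100, 5, 0.0, 100.0)],
    )
    def test_examples(self, amount, year, rate, expected):
        assert discounted_cost(amount, year, rate) == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discounted_cost(-1, 0, 0.03)
        with pytest.raises(ValueError):
            discounted_cost(1, 0, -1.5)


class TestChe:
    def test_strictly_above_threshold(self, params):
        rows = [
            {"person_id": 0, "year": 0, "cost_oop_medical": 401.0},  # case
            {"person_id": 1, "year": 0, "cost_oop_medical": 400.0},  # boundary: not a case
            {"person_id": 2, "year": 0, "cost_oop_medical": 0.0},
        ]
        res = _result_with_ledger(params, rows, [{"id": i} for i in range(3)])
        assert che_cases(res, 0.40) == 1
        assert che_cases(res, 0.10) == 2  # 400 > 100

    def test_transport_counts_toward_oop(self, params):
        rows = [{"person_id": 0, "year": 0, "cost_oop_medical": 395.0,
                 "cost_oop_transport": 10.0}]
        res = _result_with_ledger(params, rows, [{"id": 0}])
        assert che_cases(res, 0.40) == 1

    def test_non_diabetic_person_years_excluded(self, params):
        rows = [{"person_id": 0, "year": 0, "disease_state": 0, "cost_oop_medical": 900.0}]
        res = _result_with_ledger(params, rows, [{"id": 0}])
        assert che_cases(res, 0.40) == 0

    def test_monotone_in_threshold(self, params):
        coh = generate_eligible_cohort(params, 3000, seed=17)
        res = simulate(coh, build_strategy("current_standard", 0.20, 1.00, params=params),
                       params, seed=17)
        c10, c25, c40 = (che_cases(res, t) for t in (0.10, 0.25, 0.40))
        assert c10 >= c25 >= c40 > 0

    def test_invalid_threshold(self, params):
        res = _result_with_ledger(params, [{"person_id": 0, "year": 0}], [{"id": 0}])
        with pytest.raises(ValueError):
            che_cases(res, 0.0)


class TestImpoverishment:
    def test_pushed_below_line(self, params):
        line = 1.90 * 365  # 693.5
        rows = [
            {"person_id": 0, "year": 0, "cost_oop_medical": 20.0},  # 700 -> 680: case
            {"person_id": 1, "year": 0, "cost_oop_medical": 20.0},  # already below
            {"person_id": 2, "year": 0, "cost_oop_medical": 100.0},  # rich, stays above
        ]
        persons = [
            {"id": 0, "income": 700.0},
            {"id": 1, "income": 650.0},
            {"id": 2, "income": 10_000.0},
        ]
        res = _result_with_ledger(params, rows, persons)
        assert impoverishment_cases(res, params) == 1
        assert line == pytest.approx(693.5)


class TestIcer:
    @pytest.mark.parametrize(
        "cost,averted,expected",
        [(1_041_566, 38_404, 27), (142_898_661, 38_341, 3_727), (1_041_566, 479_260, 2)],
    )
    def test_positive_tradeoffs_round_to_reference(self, cost, averted, expected):
        ratio, status = icer(cost, averted)
        assert status == "ok" and round(ratio) == expected

    def test_cost_saving_is_dominant_with_signed_ratio(self):
        ratio, status = icer(-1_212_155, 38_404)
        assert status == "dominant" and round(ratio) == -32

    def test_no_effect_is_dominated_not_an_error(self):
        ratio, status = icer(100.0, 0.0)
        assert ratio is None and status == "dominated"


@pytest.fixture(scope="module")
def run(params):
    coh = generate_eligible_cohort(params, 4000, seed=23)
    strat = build_strategy("drug_therapy_only", 0.20, 1.00, params=params)
    base = simulate(coh, build_strategy("current_standard", 0.20, 1.00, params=params),
                    params, seed=23)
    res = simulate(coh, strat, params, seed=23)
    return summarize(base, params), summarize(res, params)


class TestSummaries:

    def test_cost_identity(self, run):
        for s in run:
            assert s.total_cost == pytest.approx(s.cost_government + s.cost_oop)
            assert s.dalys == pytest.approx(s.yll + s.yld)

    def test_sex_breakdowns_partition_totals(self, run):
        for s in run:
            assert sum(s.dalys_by_sex.values()) == pytest.approx(s.dalys)
            assert sum(s.che_by_sex.values()) == pytest.approx(s.che_cases[0.40])

    def test_incremental_deltas_exact(self, run):
        base, interv = run
        inc = incremental(base, interv)
        assert inc.delta_cost == interv.total_cost - base.total_cost
        assert inc.delta_dalys == interv.dalys - base.dalys
        assert inc.delta_che == interv.che_cases[0.40] - base.che_cases[0.40]

    def test_scaling_preserves_ratios(self, run):
        base, interv = run
        inc1 = incremental(base, interv)
        inc2 = incremental(scale_results(base, 7.0), scale_results(interv, 7.0))
        assert inc2.delta_cost == pytest.approx(7.0 * inc1.delta_cost)
        if inc1.icer_daly is not None:
            assert inc2.icer_daly == pytest.approx(inc1.icer_daly)

    def test_scale_identity(self, run):
        base, _ = run
        assert scale_results(base, 1.0) == base
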