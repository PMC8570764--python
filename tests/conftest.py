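"""Shared fixtures: parameter registries and small purpose-built cohorts."""

import numpy as np
import pandas as pd
import pytest

from hefsim import ParameterSet, load_parameters
from hefsim.population import Cohort


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return load_parameters()


def mutate(params: ParameterSet, path: str, value) -> ParameterSet:
    """Return a copy of the registry with one dotted-path entry replaced."""
    data = params.model_dump()
    node = data
    keys = path.split(".")
    for k in keys[:-1]:
        node = node[int(k)] if k.isdigit() else node[k]
    node[keys[-1]] = value
    return ParameterSet.model_validate(data)


def zero_mortality(params: ParameterSet) -> ParameterSet:
    """No background, diabetes, or complication mortality."""
    data = params.model_dump()
    for band in data["population"]["mortality_schedule"]:
        band["male"] = 0.0
        band["female"] = 0.0
    data["population"]["diabetes_mortality"] = 0.0
    for comp in data["complications"]:
        comp["case_fatality"] = 0.0
    return ParameterSet.model_validate(data)


def make_cohort(
    n: int,
    disease_state: int = 0,
    income: float = 300.0,
    enrolled: bool = False,
    age: float = 40.0,
    sex: int = 0,
    scale_factor: float = 1.0,
) -> Cohort:
    """A homogeneous hand-built cohort for targeted engine tests."""
    persons = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "sex": np.full(n, sex, dtype=np.int8),
            "age": np.full(n, age, dtype=float),
            "income": np.full(n, income, dtype=float),
            "hef_eligible": np.full(n, True),
            "hef_enrolled": np.full(n, enrolled),
            "disease_state": np.full(n, disease_state, dtype=np.int8),
        }
    )
    return Cohort(persons=persons, scale_factor=scale_factor, seed=0)
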