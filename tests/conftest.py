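import numpy as np
import pandas as pd
import pytest

from lifegap.lifetable import MAX_AGE, LifeTable, make_life_table
from lifegap.synthetic import Cohort, SimScenario, default_life_table


@pytest.fixture(scope="session")
def scenario() -> SimScenario:
    """Small but structurally complete study scenario."""
    return SimScenario(n_areas=8, n_per_area=2000, seed=13)


@pytest.fixture(scope="session")
def life_table(scenario) -> LifeTable:
    return default_life_table(scenario)


@pytest.fixture(scope="session")
def flat_table() -> LifeTable:
    """Life table with constant annual q = 0.1 at every age below the cap."""
    n_years = 120
    q = np.full((2, n_years, MAX_AGE + 1), 0.1)
    q[:, :, MAX_AGE] = 1.0
    return LifeTable(year0=2000, q=q)


def build_cohort(follow_months, events, area_id="A", sex="F", age=65, year=2001) -> Cohort:
    n = len(follow_months)
    return Cohort(
        area_id,
        pd.DataFrame(
            {
                "id": np.arange(n),
                "sex": sex,
                "age_start": age,
                "start_year": year,
                "follow_months": follow_months,
                "event": events,
            }
        ),
    )


@pytest.fixture
def tiny_cohort() -> Cohort:
    return build_cohort([2, 3, 5, 6], [1, 0, 1, 0])
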