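import numpy as np
import pandas as pd
import pytest

from rdscentral import CohortConfig, simulate_cohort


def respondent_table(rows, extra_columns=None):
    """Build a respondent table from (respondent_id, city, recruiter_id) tuples."""
    table = pd.DataFrame(rows, columns=["respondent_id", "city", "recruiter_id"])
    for name, values in (extra_columns or {}).items():
        table[name] = values
    return table


@pytest.fixture(scope="session")
def small_cohort():
    """A compact deterministic cohort: one city, guaranteed sizeable components."""
    config = CohortConfig(
        n_cities=1,
        seeds_per_city=30,
        recruit_count_dist=(0.25, 0.30, 0.25, 0.20, 0.0, 0.0, 0.0),
        max_waves=8,
        missing_rate=0.03,
        rng_seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default (study-scale) synthetic cohort, shared across tests."""
    return simulate_cohort(CohortConfig(rng_seed=11))
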