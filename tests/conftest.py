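import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import habsuit as hs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def roster():
    return hs.default_roster()


@pytest.fixture(scope="session")
def niche():
    return hs.default_niche()


@pytest.fixture(scope="session")
def study_data():
    """The default virtual-species dataset at the study's sample sizes."""
    records, niche, specs = hs.make_study_dataset(seed=12345)
    return records, niche, specs


@pytest.fixture(scope="session")
def complete_pools(study_data):
    """(presences, backgrounds) with all candidate variables observed."""
    records, _, specs = study_data
    complete = hs.filter_complete(records, [s.name for s in specs])
    return (
        complete[complete["status"] == "presence"],
        complete[complete["status"] == "background"],
    )


@pytest.fixture(scope="session")
def fitted_hpcs(study_data):
    """One HPC per candidate variable, fitted from the presence records."""
    records, _, specs = study_data
    presences = records[records["status"] == "presence"]
    hpcs = []
    for i, spec in enumerate(specs):
        values = presences[spec.name].dropna()
        if spec.is_continuous:
            hpcs.append(hs.fit_trapezoid(values.astype(float), spec.name,
                                         n_boot=50, seed=100 + i))
        else:
            hpcs.append(hs.fit_categorical(values, records[spec.name].dropna(),
                                           spec.name, n_boot=50, seed=100 + i))
    return hpcs


def toy_records(values_by_column: dict, status: str = "background") -> pd.DataFrame:
    """Small helper: build a record table from plain columns."""
    n = len(next(iter(values_by_column.values())))
    base = {
        "site_id": [f"t{i}" for i in range(n)],
        "x": np.arange(n, dtype=float),
        "y": np.zeros(n),
        "date": pd.Timestamp("2015-06-01"),
        "status": status,
    }
    base.update(values_by_column)
    return pd.DataFrame(base)
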