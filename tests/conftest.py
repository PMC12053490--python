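import numpy as np
import pandas as pd
import pytest

import woundcea as w


@pytest.fixture(scope="session")
def life_table():
    return w.bundled_life_table()


@pytest.fixture(scope="session")
def base_config():
    return w.default_config()


@pytest.fixture(scope="session")
def trial_2k(life_table):
    """Mid-size synthetic trial at default truths, shared across tests."""
    spec = w.CohortSpec(n_patients=2000)
    return w.generate_cohort(spec, w.TruthParams(), life_table, seed=20)


def make_trial_frames(rows, eq5d_rows=None, resource_rows=None):
    """Hand-built minimal trial for closed-form estimator checks."""
    patients = pd.DataFrame(rows)
    eq5d = pd.DataFrame(eq5d_rows or [], columns=["patient_id", "day", "unhealed", "index"])
    resources = pd.DataFrame(
        resource_rows or [],
        columns=["patient_id", "window_start", "window_end", "unhealed_days", "item", "count"],
    )
    return w.SyntheticTrial(patients=patients, eq5d=eq5d, resources=resources)


@pytest.fixture
def toy_table():
    """Two-row life table: one open age, then the absorbing cap."""
    return w.LifeTable(ages=np.array([62, 63]), qx=np.array([0.01, 1.0]))
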