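import numpy as np
import pandas as pd
import pytest

from msmhazard import CohortPanel, DGPConfig, generate_cohort, load_fixture


def make_panel(rows, T=36, **baseline_overrides):
    """Build a small CohortPanel from per-visit dicts.

    ``rows`` is a list of dicts with at least patient_id and visit; every
    missing column is filled with a benign default so tests only spell out
    what they care about.
    """
    df = pd.DataFrame(rows)
    defaults = {
        "treatment": 0, "event_death": 0, "event_cvd": 0, "censored": 0,
        "age": 65.0, "sex_male": 1, "bmi": 22.0, "diabetes": 0,
        "hd_vintage": 60.0, "baseline_treatment": 0, "baseline_ua": 7.0,
    }
    defaults.update(baseline_overrides)
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return CohortPanel(df, T=T)


@pytest.fixture
def tiny_panel():
    """3 patients x 3 visits with a uric-acid lab."""
    rows = []
    for pid, ua0 in [(1, 5.0), (2, 7.0), (3, 9.0)]:
        for v in range(1, 4):
            rows.append({"patient_id": pid, "visit": v,
                         "ua": ua0 + 0.1 * v, "baseline_ua": ua0})
    return make_panel(rows)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One medium recovery-A cohort shared across tests (seed 0)."""
    fix = load_fixture("recovery-A")
    return generate_cohort(fix.dgp.with_(n_patients=800)), fix


@pytest.fixture(scope="session")
def small_null_config():
    return load_fixture("null").dgp.with_(n_patients=400, T=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
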