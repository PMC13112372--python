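import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """6-sample toy count matrix with one obviously shifted gene."""
    from neuroimmune.expression import CountMatrix

    counts = pd.DataFrame(
        {
            "WT1": [100, 50, 10, 400],
            "WT2": [110, 55, 12, 410],
            "WT3": [90, 45, 9, 390],
            "DS1": [400, 52, 11, 405],
            "DS2": [420, 48, 10, 395],
            "DS3": [380, 50, 12, 400],
        },
        index=["Up1", "Flat1", "Flat2", "Flat3"],
    )
    groups = pd.Series(
        ["control"] * 3 + ["case"] * 3,
        index=["WT1", "WT2", "WT3", "DS1", "DS2", "DS3"],
    )
    return CountMatrix(counts, groups)


@pytest.fixture
def toy_cohort():
    """Deterministic 8-record cohort with two groups."""
    return pd.DataFrame(
        {
            "group": ["SeLECTS"] * 4 + ["DRE"] * 4,
            "age_onset_years": [7, 8, 6, 5, 1, 2, 1.5, 0.5],
            "sex": ["male", "female", "male", "male", "female", "male", "female", "male"],
            "bmi": [17.0, 16.5, 18.0, 17.2, 15.5, 16.0, 15.8, 16.2],
            "wbc": [6.0, 6.5, 6.2, 5.9, 7.0, 6.8, 7.2, 6.9],
            "neutrophil_pct": [45, 44, 46, 43, 52, 50, 51, 49],
            "lymphocyte_pct": [45, 46, 44, 47, 38, 40, 39, 41],
            "platelets": [230, 225, 240, 228, 260, 250, 255, 245],
            "crp": [0.06, 0.05, 0.07, 0.06, 0.11, 0.10, 0.12, 0.09],
        }
    )
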