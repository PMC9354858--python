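import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_items(rows):
    """Build an item table from (patient, week, instrument, item, score, max) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "week", "instrument", "item_id", "score", "max_score"]
    )


@pytest.fixture(scope="session")
def scale_map():
    from sldnet.scales import default_scale_map

    return default_scale_map()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full item-level synthetic cohort shared across tests."""
    from sldnet.simulate import generate_cohort, primary_like

    return generate_cohort(primary_like(n_patients=30, seed=42))


@pytest.fixture(scope="session")
def complete_series():
    """One fully observed random 13x9 symptom series."""
    from sldnet.scales import SymptomSeries

    rng = np.random.default_rng(7)
    return SymptomSeries("full", rng.random((13, 9)), observed_weeks=13)
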