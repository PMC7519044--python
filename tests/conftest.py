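import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gaitwomac as gw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return gw.CohortConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default 375-subject synthetic cohort, shared across tests."""
    return gw.generate_cohort(default_config)


@pytest.fixture(scope="session")
def full_registry():
    return gw.default_registry()


@pytest.fixture(scope="session")
def feature_frame(cohort, full_registry):
    """Feature matrix (DataFrame) for the shared cohort."""
    fm = gw.extract_matrix([s.trial for s in cohort], full_registry)
    return fm.drop_masked_features().to_frame()


@pytest.fixture(scope="session")
def cohort_labels(cohort):
    classes = pd.Series(
        {s.trial.subject_id: gw.classify_total(s.womac).label for s in cohort}, name="class"
    )
    totals = pd.Series({s.trial.subject_id: s.womac.total for s in cohort}, name="total")
    return classes, totals


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
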