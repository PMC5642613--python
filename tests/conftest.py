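import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import bcellhcc as bc

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with annotations, nothing degenerate."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.normal(8, 1, size=(3, 4)),
                          index=["G1", "G2", "G3"],
                          columns=["S1", "S2", "S3", "S4"])
    ann = bc.make_annotations(
        ["S1", "S2", "S3", "S4"],
        entity=["HCC", "HCC", "LUNG", "LUNG"],
        platform=["A", "A", "B", "B"],
        tissue=["tumor", "non_tumor", "tumor", "non_tumor"],
        patient_id=["P1", "P1", "P2", "P2"])
    return bc.ExpressionMatrix(values, ann)


@pytest.fixture(scope="session")
def default_ihc_config():
    return bc.IHCConfig.default()


@pytest.fixture(scope="session")
def default_validation_config():
    return bc.ValidationConfig.default()


@pytest.fixture(scope="session")
def default_pancancer_config():
    return bc.PanCancerConfig.default()


@pytest.fixture(scope="session")
def ihc_cohort(default_ihc_config):
    return bc.generate_ihc_cohort(default_ihc_config, seed=11)


@pytest.fixture(scope="session")
def validation_cohort(default_validation_config):
    return bc.generate_validation_cohort(default_validation_config, seed=11)
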