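import numpy as np
import pandas as pd
import pytest

from aaarisk import CohortDataset, CohortGeneratorConfig, PredictiveDistribution, generate_cohort
from aaarisk.cohort_data import FEATURE_COLUMNS, PROPERTY_COLUMNS
from aaarisk.synthetic_cohort import default_log_theta_corr


def make_dataset(features: np.ndarray, properties: np.ndarray, patient_ids=None) -> CohortDataset:
    """Assemble a CohortDataset from raw arrays (features may be < 8 columns)."""
    features = np.atleast_2d(np.asarray(features, float))
    cols = FEATURE_COLUMNS[: features.shape[1]]
    n = len(features)
    return CohortDataset(
        patient_ids=np.arange(1, n + 1) if patient_ids is None else np.asarray(patient_ids),
        features=pd.DataFrame(features, columns=cols),
        properties=pd.DataFrame(np.atleast_2d(properties), columns=PROPERTY_COLUMNS),
    )


@pytest.fixture(scope="session")
def small_cohort() -> CohortDataset:
    """20 patients, 1-2 samples each, default cohort statistics."""
    return generate_cohort(
        CohortGeneratorConfig(
            n_patients=20, samples_per_patient={1: 0.5, 2: 0.5}, seed=11
        )
    )


@pytest.fixture(scope="session")
def pat17_predictive() -> PredictiveDistribution:
    """Predictive distribution with the demonstration patient's log moments."""
    mu = np.array([0.415, 4.504, 7.723, 6.729])
    sd = np.array([0.088, 0.967, 0.817, 0.174])
    return PredictiveDistribution(mu, default_log_theta_corr() * np.outer(sd, sd))
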