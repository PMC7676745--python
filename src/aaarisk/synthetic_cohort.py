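"""Seeded generator of cohorts with the database's statistical structure.

Emulates a tensile-test database: each patient contributes one feature
vector (geometry + hemogram, Gaussian marginals with the cohort's moments)
and one or more tissue samples whose log wall properties are a noisy linear
function of the standardized features plus correlated multivariate Gaussian
noise.  Marginals of log [t, alpha, beta, sigma_gamma] default to the cohort
moments over the 251-sample database; cross-correlations default to the
strongest predictive correlations reported for one demonstration patient
(the cohort's own pairwise correlations are not published) and are fully
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_data import (
    FEATURE_COLUMNS,
    PROPERTY_COLUMNS,
    CohortDataset,
    write_cohort,
)

__all__ = [
    "CohortGeneratorConfig",
    "default_log_theta_corr",
    "generate_cohort",
    "inject_missing",
    "write_synthetic_cohort",
]

# cohort marginals of log [t, alpha, beta, sigma_gamma] over the database
_LOG_THETA_MEAN = (0.484, 4.543, 7.685, 6.704)
_LOG_THETA_SD = (0.105, 1.036, 0.758, 0.183)

# feature moments (cohort column): order matches FEATURE_COLUMNS
_FEATURE_MEANS = (62.91, 24.10, 111.84, 24.58, 221.33, 13.27, 30.39, 89.95)
_FEATURE_SDS = (17.57, 11.19, 28.30, 6.55, 82.10, 2.20, 2.46, 6.61)


def default_log_theta_corr() -> np.ndarray:
    """Default 4x4 correlation of log properties (order t, alpha, beta, sg)."""
    c = np.eye(4)
    pairs = {(0, 3): -0.3214, (2, 3): 0.2274, (0, 2): -0.1966, (1, 2): 0.1413}
    for (i, j), r in pairs.items():
        c[i, j] = c[j, i] = r
    return c


@dataclass
class CohortGeneratorConfig:
    """Study conditions for one synthetic cohort draw.

    ``samples_per_patient`` maps sample counts to probabilities (defaults to
    a mixture averaging ~2.2 samples/patient, matching 251 samples from 113
    patients).  ``link_weights`` is an 8x4 matrix coupling standardized
    features to log properties; zero by default (pure cohort noise).
    """

    n_patients: int = 113
    samples_per_patient: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}
    )
    log_theta_mean: np.ndarray = field(default_factory=lambda: np.array(_LOG_THETA_MEAN))
    log_theta_sd: np.ndarray = field(default_factory=lambda: np.array(_LOG_THETA_SD))
    log_theta_corr: np.ndarray = field(default_factory=default_log_theta_corr)
    link_weights: np.ndarray = field(default_factory=lambda: np.zeros((8, 4)))
    feature_means: np.ndarray = field(default_factory=lambda: np.array(_FEATURE_MEANS))
    feature_sds: np.ndarray = field(default_factory=lambda: np.array(_FEATURE_SDS))
    noise_sd: np.ndarray | None = None  # defaults to log_theta_sd
    seed: int = 0

    def noise_covariance(self) -> np.ndarray:
        sd = np.asarray(self.log_theta_sd if self.noise_sd is None else self.noise_sd, float)
        corr = np.asarray(self.log_theta_corr, float)
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("log_theta_corr must be symmetric with unit diagonal")
        if np.any(sd <= 0) or np.any(np.asarray(self.feature_sds) <= 0):
            raise ValueError("all standard deviations must be strictly positive")
        cov = corr * np.outer(sd, sd)
        return cov


def generate_cohort(config: CohortGeneratorConfig) -> CohortDataset:
    """Draw one cohort; identical config (incl. seed) => identical cohort."""
    cov = config.noise_covariance()
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("assembled log-property covariance is not positive definite") from exc

    rng = np.random.default_rng(config.seed)
    counts = np.array(sorted(config.samples_per_patient))
    probs = np.array([config.samples_per_patient[c] for c in counts], dtype=float)
    probs = probs / probs.sum()

    W = np.asarray(config.link_weights, dtype=float)
    if W.shape != (8, 4):
        raise ValueError(f"link_weights must be 8x4, got {W.shape}")
    mu = np.asarray(config.log_theta_mean, dtype=float)

    ids, feat_rows, log_theta_rows = [], [], []
    for pid in range(1, config.n_patients + 1):
        z = rng.standard_normal(8)
        features = np.asarray(config.feature_means) + z * np.asarray(config.feature_sds)
        n_samples = int(rng.choice(counts, p=probs))
        for _ in range(n_samples):
            eps = chol @ rng.standard_normal(4)
            log_theta_rows.append(mu + W.T @ z + eps)
            feat_rows.append(features)
            ids.append(pid)

    return CohortDataset(
        patient_ids=np.array(ids),
        features=pd.DataFrame(np.array(feat_rows), columns=FEATURE_COLUMNS),
        properties=pd.DataFrame(np.exp(np.array(log_theta_rows)), columns=PROPERTY_COLUMNS),
    )


def inject_missing(dataset: CohortDataset, rate: float, seed: int = 0) -> CohortDataset:
    """Blank out a fraction of feature cells at random (for testing filters)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    feats = dataset.features.copy().astype(float)
    mask = rng.random(feats.shape) < rate
    if mask.all(axis=None):
        warnings.warn("missingness mask blanked every cell")
    feats[mask] = np.nan
    return CohortDataset(
        patient_ids=dataset.patient_ids.copy(),
        features=feats,
        properties=dataset.properties.copy(),
    )


def write_synthetic_cohort(config: CohortGeneratorConfig, out_prefix: str) -> tuple[str, str]:
    """Generate and write ``<prefix>_noninvasive.csv`` / ``<prefix>_invasive.csv``."""
    dataset = generate_cohort(config)
    paths = (f"{out_prefix}_noninvasive.csv", f"{out_prefix}_invasive.csv")
    write_cohort(dataset, *paths)
    return paths
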