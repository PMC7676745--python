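"""Rupture-risk indices: Monte-Carlo P_rupt and deterministic comparators.

The probability of rupture is the expectation, under the joint predictive
distribution of the log wall properties, of the event that the peak wall
stress exceeds the wall strength:

    P_rupt = E_{p(log Theta)}[ 1{ log sigma_vm_max(theta) > log sigma_gamma } ],

estimated by seeded Monte Carlo with the Kriging surrogate standing in for
the stress model.  Comparators: the stress at the predictive mean
parameters, the rupture potential index RPI = stress / mean strength, and
the PRRI, which keeps only independent cohort-style uncertainty in wall
thickness and wall strength.  A closed-form normal-comparison oracle is
included for validating the Monte-Carlo estimator under independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .forward_model import WallParams
from .mgp import PredictiveDistribution

__all__ = [
    "RiskResult",
    "prob_rupture_mc",
    "prob_rupture_closed_form",
    "rpi",
    "rpi_from_values",
    "prri",
    "compute_risk",
]


@dataclass
class RiskResult:
    """All indices for one patient, plus Monte-Carlo diagnostics."""

    p_rupt: float
    sigma_at_mean: float  # [kPa]
    rpi: float
    prri: float
    n_eval: int
    mc_standard_error: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_rupt <= 1.0 and 0.0 <= self.prri <= 1.0):
            raise ValueError("p_rupt and prri must lie in [0, 1]")
        if self.rpi <= 0:
            raise ValueError("rpi must be positive")


def _log_stress_fn(surrogate):
    """Accept a Kriging-like model (``predict_mean``) or a plain callable."""
    if hasattr(surrogate, "predict_mean"):
        return lambda theta: np.asarray(surrogate.predict_mean(theta), float)
    return lambda theta: np.asarray(surrogate(theta), float)


def _sample_log_theta(
    predictive: PredictiveDistribution, n: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    cov = predictive.sigma_log_theta
    if method == "cholesky":
        fac = np.linalg.cholesky(cov)
    elif method == "eigh":
        w, V = np.linalg.eigh(cov)
        fac = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    else:
        raise ValueError(f"unknown factorization {method!r}")
    z = rng.standard_normal((n, 4))
    return predictive.mu_log_theta[None, :] + z @ fac.T


def prob_rupture_mc(
    surrogate,
    predictive: PredictiveDistribution,
    n_eval: int = 10_000,
    seed: int = 0,
    factorization: str = "cholesky",
) -> tuple[float, float]:
    """Monte-Carlo estimate of P_rupt and its binomial standard error.

    Joint (correlated) samples of log Theta are drawn via a factorization of
    the predictive covariance; for each, the surrogate's mean log stress at
    the sampled (t, alpha, beta) is compared strictly against the sampled
    log strength (ties count as non-rupture).
    """
    rng = np.random.default_rng(seed)
    log_theta = _sample_log_theta(predictive, n_eval, rng, factorization)
    log_stress = _log_stress_fn(surrogate)(np.exp(log_theta[:, :3]))
    p_hat = float(np.mean(log_stress > log_theta[:, 3]))
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_eval))
    return p_hat, se


def prob_rupture_closed_form(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """P(X > Y) for independent X ~ N(mu1, s1^2), Y ~ N(mu2, s2^2).

    Oracle for Monte-Carlo validation.  With both spreads zero the indicator
    is a deterministic step; a tie counts as non-rupture.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = np.hypot(s1, s2)
    if denom == 0.0:
        return float(mu1 > mu2)
    return float(norm.cdf((mu1 - mu2) / denom))


def rpi_from_values(stress_kpa: float, mean_strength_kpa: float) -> float:
    """Rupture potential index from a stress and a mean wall strength [kPa]."""
    if mean_strength_kpa <= 0:
        raise ValueError("mean wall strength must be positive")
    return stress_kpa / mean_strength_kpa


def _stress_at_mean(stress_model, predictive: PredictiveDistribution) -> float:
    """Physical stress [kPa] at the predictive mean parameters exp(mu_log theta)."""
    theta_mean = WallParams(*np.exp(predictive.mu_log_theta[:3]))
    if hasattr(stress_model, "predict_mean"):  # surrogate of the log stress
        log_s = np.asarray(stress_model.predict_mean(theta_mean.as_array()), float)
        return float(np.exp(log_s.reshape(-1)[0]))
    if hasattr(stress_model, "evaluate"):  # forward model in physical units
        return float(stress_model.evaluate(theta_mean))
    log_s = np.asarray(stress_model(theta_mean.as_array()), float)
    return float(np.exp(log_s.reshape(-1)[0]))


def rpi(stress_model, predictive: PredictiveDistribution) -> float:
    """RPI: stress at the predictive mean over the predictive mean strength.

    The mean strength is the log-normal mean exp(mu_log + sigma_log^2 / 2)
    in physical space.  ``stress_model`` may be a trained surrogate (of the
    log stress) or a forward model.
    """
    mu_sg = float(np.exp(predictive.mu_log_theta[3] + 0.5 * predictive.sigma_log_theta[3, 3]))
    return rpi_from_values(_stress_at_mean(stress_model, predictive), mu_sg)


def prri(
    surrogate,
    predictive: PredictiveDistribution,
    n_eval: int = 10_000,
    seed: int = 0,
    literal: bool = False,
) -> float:
    """Probabilistic rupture risk index with independent t / strength marginals.

    Samples log t and log sigma_gamma independently from their predictive
    marginals; alpha and beta stay fixed at their predictive (log-space)
    means.  The stress is evaluated at the sampled thickness.  With
    ``literal=True`` the as-printed variant is used instead: the stress is
    held at mu_log_t and compared against mu_log_sigma_gamma, collapsing the
    index to a deterministic 0/1 step.
    """
    mu = predictive.mu_log_theta
    sd = predictive.marginal_sd
    f = _log_stress_fn(surrogate)
    if literal:
        theta = np.exp(np.array([[mu[0], mu[1], mu[2]]]))
        return float(f(theta)[0] > mu[3])
    rng = np.random.default_rng(seed)
    log_t = mu[0] + sd[0] * rng.standard_normal(n_eval)
    log_sg = mu[3] + sd[3] * rng.standard_normal(n_eval)
    theta = np.column_stack(
        [np.exp(log_t), np.full(n_eval, np.exp(mu[1])), np.full(n_eval, np.exp(mu[2]))]
    )
    return float(np.mean(f(theta) > log_sg))


def compute_risk(
    surrogate,
    predictive: PredictiveDistribution,
    n_eval: int = 10_000,
    seed: int = 0,
) -> RiskResult:
    """Assemble P_rupt, the stress at the mean, RPI and PRRI for one patient."""
    p_hat, se = prob_rupture_mc(surrogate, predictive, n_eval=n_eval, seed=seed)
    if p_hat in (0.0, 1.0):
        warnings.warn(
            f"Monte-Carlo rupture probability saturated at {p_hat}; "
            "n_eval may be too small to resolve it"
        )
    return RiskResult(
        p_rupt=p_hat,
        sigma_at_mean=_stress_at_mean(surrogate, predictive),
        rpi=rpi(surrogate, predictive),
        prri=prri(surrogate, predictive, n_eval=n_eval, seed=seed + 1),
        n_eval=n_eval,
        mc_standard_error=se,
    )
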