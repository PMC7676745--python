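"""Density- and stress-weighted active training of the Kriging surrogate.

Forward-model evaluations are expensive (a finite-element solve in the full
pipeline), so training points are chosen sequentially where the surrogate is
uncertain AND the patient's predictive density of the wall properties is
high AND the predicted stress is high:

    psi(Theta) = delta_log_stress(theta) * p(log Theta) * mu_log_stress(theta),

with theta the (t, alpha, beta) components of Theta and the strength
component participating only through the density.  The acquisition grid is
a seeded Latin-hypercube sample over the mean +/- 3 sigma log-space box
(tensor grids are infeasible in 4-D at 10,000 points, and the density must
be an explicit weight, not the sampling distribution).  Training stops when
the grid average psi_hat of the objective changes by at most ``tol``
between iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, qmc

from .forward_model import ForwardModel, WallParams
from .kriging import KrigingModel, kriging_fit
from .mgp import PredictiveDistribution

__all__ = [
    "ActiveLearningConfig",
    "AcquisitionGrid",
    "build_acquisition_grid",
    "acquisition_psi",
    "next_point",
    "train_surrogate_active",
]

logger = logging.getLogger(__name__)


@dataclass
class ActiveLearningConfig:
    n_init: int = 8
    n_grid: int = 10_000
    n_eval: int = 10_000
    tol: float = 1.0e-4
    max_iters: int = 200
    seed: int = 0
    box_sigmas: float = 3.0
    kriging_restarts: int = 6
    max_consecutive_failures: int = 3

    def __post_init__(self) -> None:
        if self.n_init < 8:
            raise ValueError("n_init must be at least 8 (trilinear basis rank)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class AcquisitionGrid:
    """Candidate points in log Theta space with their predictive densities."""

    points: np.ndarray    # (n_grid, 4) log [t, alpha, beta, sigma_gamma]
    densities: np.ndarray  # p(log Theta) at each point, >= 0

    def __post_init__(self) -> None:
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")


def _log_box(predictive: PredictiveDistribution, sigmas: float) -> tuple[np.ndarray, np.ndarray]:
    sd = predictive.marginal_sd
    return predictive.mu_log_theta - sigmas * sd, predictive.mu_log_theta + sigmas * sd


def build_acquisition_grid(
    predictive: PredictiveDistribution, n_grid: int, seed: int, box_sigmas: float = 3.0
) -> AcquisitionGrid:
    """Seeded Latin-hypercube grid over the +/- box_sigmas log-space box."""
    lo, hi = _log_box(predictive, box_sigmas)
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    pts = lo[None, :] + sampler.random(n_grid) * (hi - lo)[None, :]
    dens = multivariate_normal(
        mean=predictive.mu_log_theta, cov=predictive.sigma_log_theta, allow_singular=True
    ).pdf(pts)
    return AcquisitionGrid(points=pts, densities=np.atleast_1d(dens))


def _grid_psi(surrogate: KrigingModel, grid: AcquisitionGrid) -> np.ndarray:
    theta = np.exp(grid.points[:, :3])
    mean, sd = surrogate.predict(theta)
    mean = np.asarray(mean, float)
    if np.any(mean < 0):
        warnings.warn("negative predicted log stress (sub-kPa); clamped to 0 in psi")
        mean = np.clip(mean, 0.0, None)
    return sd * grid.densities * mean


def acquisition_psi(surrogate: KrigingModel, point: np.ndarray, density: float) -> float:
    """psi at one log-Theta point: predictive sd x density x predictive mean."""
    grid = AcquisitionGrid(points=np.atleast_2d(point), densities=np.atleast_1d(float(density)))
    return float(_grid_psi(surrogate, grid)[0])


def _next_index(surrogate: KrigingModel, grid: AcquisitionGrid) -> int:
    if grid.points.shape[0] == 0:
        raise ValueError("acquisition grid is empty")
    psi = _grid_psi(surrogate, grid)
    if np.all(psi == 0):
        logger.warning("all acquisition values are zero; falling back to the densest point")
        return int(np.argmax(grid.densities))
    return int(np.argmax(psi))


def next_point(surrogate: KrigingModel, grid: AcquisitionGrid) -> WallParams:
    """Grid point maximizing psi (ties -> lowest index); theta components only."""
    idx = _next_index(surrogate, grid)
    t, a, b = np.exp(grid.points[idx, :3])
    return WallParams(t=t, alpha=a, beta=b)


@dataclass
class TrainingLog:
    """Per-iteration record of the active-learning run."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_forward_evaluations: int = 0
    psi_history: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def train_surrogate_active(
    forward: ForwardModel,
    predictive: PredictiveDistribution,
    config: ActiveLearningConfig | None = None,
) -> tuple[KrigingModel, TrainingLog]:
    """Actively train the Kriging surrogate against a forward model.

    Initial design: the predictive mean itself plus ``n_init - 1`` seeded
    Latin-hypercube points over the +/- 3 sigma log box of (t, alpha, beta).
    Then per iteration: pick the acquisition maximizer, evaluate the forward
    model there, refit, and recompute the grid average psi_hat; stop when
    |psi_hat_iter - psi_hat_{iter-1}| <= tol (psi_hat_0 = 0) or at
    ``max_iters``.  Fully reproducible given (seed, config, forward model).
    """
    config = config or ActiveLearningConfig()
    if np.min(np.linalg.eigvalsh(predictive.sigma_log_theta)) <= 0:
        raise ValueError("predictive covariance must be positive definite")

    lo, hi = _log_box(predictive, config.box_sigmas)
    sampler = qmc.LatinHypercube(d=3, seed=config.seed)
    init_log = lo[None, :3] + sampler.random(config.n_init - 1) * (hi - lo)[None, :3]
    init_log = np.vstack([predictive.mu_log_theta[None, :3], init_log])

    X, y, rows = [], [], []
    for lp in init_log:
        p = WallParams(*np.exp(lp))
        stress = forward.evaluate(p)
        X.append(p.as_array())
        y.append(np.log(stress))
        rows.append({"iteration": 0, "psi_hat": np.nan, "t": p.t, "alpha": p.alpha,
                     "beta": p.beta, "stress_kpa": stress})
    n_evals = len(y)

    surrogate = kriging_fit(
        np.array(X), np.array(y), restarts=config.kriging_restarts, seed=config.seed
    )
    grid = build_acquisition_grid(predictive, config.n_grid, config.seed + 1, config.box_sigmas)
    active = np.ones(config.n_grid, dtype=bool)

    psi_prev = 0.0  # psi_hat_0
    psi_hat = float(np.mean(_grid_psi(surrogate, grid)))
    history = [psi_hat]
    iteration = 1
    failures = 0
    while abs(psi_hat - psi_prev) > config.tol and iteration <= config.max_iters:
        sub = AcquisitionGrid(points=grid.points[active], densities=grid.densities[active])
        sub_idx = _next_index(surrogate, sub)
        t, a, b = np.exp(sub.points[sub_idx, :3])
        proposal = WallParams(t=t, alpha=a, beta=b)
        try:
            stress = forward.evaluate(proposal)
        except Exception as exc:  # forward-model failure: penalize and skip the point
            failures += 1
            logger.warning("forward model failed at %s: %s", proposal, exc)
            if failures > config.max_consecutive_failures:
                raise RuntimeError(
                    f"forward model failed {failures} times in a row; aborting"
                ) from exc
            active[np.flatnonzero(active)[sub_idx]] = False
            continue
        failures = 0
        n_evals += 1
        X.append(proposal.as_array())
        y.append(np.log(stress))
        surrogate = kriging_fit(
            np.array(X), np.array(y), restarts=config.kriging_restarts, seed=config.seed
        )
        psi_prev = psi_hat
        psi_hat = float(np.mean(_grid_psi(surrogate, grid)))
        history.append(psi_hat)
        rows.append({"iteration": iteration, "psi_hat": psi_hat, "t": proposal.t,
                     "alpha": proposal.alpha, "beta": proposal.beta, "stress_kpa": stress})
        iteration += 1

    log = TrainingLog(
        records=pd.DataFrame(rows), n_forward_evaluations=n_evals, psi_history=history
    )
    return surrogate, log
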