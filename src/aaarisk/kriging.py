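"""Universal Kriging surrogate of the log peak wall stress.

Noise-free GP interpolation of log sigma_vm_max over theta = (t, alpha,
beta) with an explicit trilinear trend h(theta) = [1, t, a, b, ta, tb, ab,
tab] under a vague coefficient prior, so any target inside span(h) is
reproduced exactly.  The kernel is a squared exponential with one variance
zeta1 and per-dimension (squared) length scales Lambda = diag(zeta2, zeta3,
zeta4):

    k(x, x') = zeta1 exp(-1/2 (x - x')^T Lambda^-1 (x - x')).

Inputs are standardized internally to the [0, 1] training box before kernel
and trend evaluation — t (~mm) and beta (~thousands of kPa) differ by three
orders of magnitude, and a per-dimension affine map leaves span(h)
unchanged.  A relative nugget (1e-10 zeta1) keeps the interpolation system
conditioned.  Hyperparameters maximize the profile marginal likelihood of
the vague-prior model (the GLS quadratic and log|H K^-1 H^T| terms
included).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import contextlib

from scipy.linalg import LinAlgWarning, cho_factor, cho_solve, solve


@contextlib.contextmanager
def _quiet_linalg():
    # the relative nugget guards conditioning; scipy's ill-conditioning
    # warnings during hyperparameter search (extreme length-scale trials)
    # are expected and non-fatal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LinAlgWarning)
        yield
from scipy.optimize import minimize
from scipy.stats import qmc

from .forward_model import WallParams

__all__ = [
    "KrigingHyperparams",
    "KrigingModel",
    "trilinear_basis",
    "kriging_fit",
    "kriging_predict",
]

_BASIS_SIZE = 8


def trilinear_basis(params: WallParams | np.ndarray) -> np.ndarray:
    """h(theta) = [1, t, a, b, t*a, t*b, a*b, t*a*b] in raw coordinates."""
    th = params.as_array() if isinstance(params, WallParams) else np.asarray(params, float)
    t, a, b = th
    return np.array([1.0, t, a, b, t * a, t * b, a * b, t * a * b])


def _basis_matrix(X: np.ndarray) -> np.ndarray:
    """8 x n matrix of trilinear basis evaluations (columns = points)."""
    t, a, b = X[:, 0], X[:, 1], X[:, 2]
    return np.stack(
        [np.ones_like(t), t, a, b, t * a, t * b, a * b, t * a * b], axis=0
    )


@dataclass
class KrigingHyperparams:
    """Signal variance and per-dimension squared length scales (standardized coords)."""

    zeta1: float
    lengthscales: np.ndarray  # diag of Lambda: (zeta2, zeta3, zeta4)

    def __post_init__(self) -> None:
        self.lengthscales = np.asarray(self.lengthscales, float)
        if self.zeta1 <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("all Kriging hyperparameters must be strictly positive")


def _sq_dist(A: np.ndarray, B: np.ndarray, ls: np.ndarray) -> np.ndarray:
    As = A / np.sqrt(ls)[None, :]
    Bs = B / np.sqrt(ls)[None, :]
    d2 = (
        np.sum(As**2, axis=1)[:, None]
        + np.sum(Bs**2, axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    return np.maximum(d2, 0.0)


class KrigingModel:
    """Trained universal Kriging interpolant of log sigma_vm_max."""

    def __init__(
        self,
        X_raw: np.ndarray,
        y: np.ndarray,
        hyperparams: KrigingHyperparams,
        nugget_rel: float = 1e-10,
    ):
        self.X_raw = np.atleast_2d(np.asarray(X_raw, float))
        self.y = np.asarray(y, float).reshape(-1)
        if len(self.y) != len(self.X_raw):
            raise ValueError("inputs and outputs differ in length")
        self.hyperparams = hyperparams
        self.nugget_rel = nugget_rel
        self._fit_caches()

    # -- standardization to the [0, 1] training box -------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._box_lo[None, :]) / self._box_scale[None, :]

    def _fit_caches(self) -> None:
        self._box_lo = self.X_raw.min(axis=0)
        span = self.X_raw.max(axis=0) - self._box_lo
        self._box_scale = np.where(span > 0, span, 1.0)
        self.X = self._standardize(self.X_raw)

        # largest full-rank sub-basis (degenerate designs reduce the trend)
        from scipy.linalg import qr as _qr

        H_full = _basis_matrix(self.X)
        _, R, piv = _qr(H_full.T, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(H_full.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        rank = int(np.sum(diag > max(tol, 1e-9 * (diag[0] if diag.size else 1.0))))
        self.basis_idx = np.sort(piv[:rank])
        if rank < _BASIS_SIZE:
            warnings.warn(
                f"degenerate design: trend basis reduced from {_BASIS_SIZE} to rank {rank}"
            )
        if rank == 0:
            raise ValueError("trend basis is rank-deficient even after reduction")
        self.m = rank
        self.H = H_full[self.basis_idx, :]  # m x n

        hp = self.hyperparams
        K = hp.zeta1 * np.exp(-0.5 * _sq_dist(self.X, self.X, hp.lengthscales))
        K[np.diag_indices_from(K)] += self.nugget_rel * hp.zeta1
        self._K = K
        with _quiet_linalg():
            self._K_chol = cho_factor(K, lower=True)
            self._alpha = cho_solve(self._K_chol, self.y)      # K^-1 y
            self._G = cho_solve(self._K_chol, self.H.T)        # K^-1 H^T  (n x m)
            self._A = self.H @ self._G                         # H K^-1 H^T (m x m)
            self._A = 0.5 * (self._A + self._A.T)
            self.eta_bar = solve(self._A, self._G.T @ self.y, assume_a="pos")
            self._resid_alpha = cho_solve(self._K_chol, self.y - self.H.T @ self.eta_bar)

    @property
    def n_points(self) -> int:
        return len(self.y)

    def _kernel_cross(self, X_new: np.ndarray) -> np.ndarray:
        hp = self.hyperparams
        return hp.zeta1 * np.exp(-0.5 * _sq_dist(self.X, X_new, hp.lengthscales))

    def predict(self, params) -> tuple[np.ndarray, np.ndarray]:
        """Mean and standard deviation of log sigma_vm_max.

        Accepts a single :class:`WallParams`/3-vector or an (n, 3) array;
        returns scalars or arrays accordingly.  The variance includes the
        trend-uncertainty term r^T (H K^-1 H^T)^-1 r and is clipped at zero.
        """
        single = isinstance(params, WallParams) or np.asarray(params, float).ndim == 1
        th = params.as_array() if isinstance(params, WallParams) else np.asarray(params, float)
        X_new = self._standardize(np.atleast_2d(th))
        Ks = self._kernel_cross(X_new)                     # n x q
        h_new = _basis_matrix(X_new)[self.basis_idx, :]    # m x q
        r = h_new - self._G.T @ Ks                         # m x q
        mean = Ks.T @ self._resid_alpha + h_new.T @ self.eta_bar

        hp = self.hyperparams
        kss = hp.zeta1 * (1.0 + self.nugget_rel)
        with _quiet_linalg():
            var_gp = kss - np.sum(Ks * cho_solve(self._K_chol, Ks), axis=0)
            var_trend = np.sum(r * solve(self._A, r, assume_a="pos"), axis=0)
        var = np.clip(var_gp + var_trend, 0.0, None)
        sd = np.sqrt(var)
        if single:
            return float(mean[0]), float(sd[0])
        return mean, sd

    def predict_mean(self, params) -> np.ndarray:
        return self.predict(params)[0]

    def log_marginal(self) -> float:
        """Vague-prior profile log likelihood (GLS form)."""
        y = self.y
        with _quiet_linalg():
            quad = -0.5 * y @ self._alpha + 0.5 * (self._G.T @ y) @ solve(
                self._A, self._G.T @ y, assume_a="pos"
            )
        logdet_K = 2.0 * np.sum(np.log(np.diag(self._K_chol[0])))
        sign, logdet_A = np.linalg.slogdet(self._A)
        if sign <= 0:
            return -np.inf
        n, m = self.n_points, self.m
        return float(quad - 0.5 * logdet_K - 0.5 * logdet_A - 0.5 * (n - m) * np.log(2.0 * np.pi))

    def with_point(self, params: WallParams | np.ndarray, value: float) -> "KrigingModel":
        """New model including one extra training point (same hyperparameters)."""
        th = params.as_array() if isinstance(params, WallParams) else np.asarray(params, float)
        return KrigingModel(
            np.vstack([self.X_raw, th]),
            np.append(self.y, value),
            self.hyperparams,
            nugget_rel=self.nugget_rel,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "X": self.X_raw.tolist(),
                "y": self.y.tolist(),
                "zeta1": self.hyperparams.zeta1,
                "lengthscales": self.hyperparams.lengthscales.tolist(),
                "nugget_rel": self.nugget_rel,
                "basis": "trilinear",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KrigingModel":
        doc = json.loads(text)
        return cls(
            np.array(doc["X"]),
            np.array(doc["y"]),
            KrigingHyperparams(doc["zeta1"], np.array(doc["lengthscales"])),
            nugget_rel=doc["nugget_rel"],
        )


def kriging_fit(
    inputs: np.ndarray,
    outputs: np.ndarray,
    restarts: int = 8,
    seed: int = 0,
    nugget_rel: float = 1e-10,
    maxiter: int = 100,
) -> KrigingModel:
    """Fit hyperparameters by maximizing the vague-prior marginal likelihood.

    ``inputs`` is (n, 3) raw theta (or a list of :class:`WallParams`);
    n >= 8 points with a full-rank trilinear design are expected (degenerate
    designs reduce the basis with a warning).  Deterministic given ``seed``.
    """
    X = np.array(
        [p.as_array() if isinstance(p, WallParams) else np.asarray(p, float) for p in inputs]
    )
    y = np.asarray(outputs, float).reshape(-1)
    if len(X) < _BASIS_SIZE:
        warnings.warn(
            f"only {len(X)} training points; the full trilinear trend needs >= {_BASIS_SIZE}"
        )

    y_var = max(np.var(y), 1e-12)

    def objective(v: np.ndarray) -> float:
        try:
            model = KrigingModel(
                X, y, KrigingHyperparams(np.exp(v[0]), np.exp(v[1:4])), nugget_rel=nugget_rel
            )
            return -model.log_marginal()
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    # seeded Latin-hypercube multistart in log space
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = sampler.random(max(1, restarts))
    lo = np.array([np.log(y_var) - 3.0, *np.log([1e-3] * 3)])
    hi = np.array([np.log(y_var) + 3.0, *np.log([4.0] * 3)])
    starts = lo[None, :] + starts * (hi - lo)[None, :]

    best_v, best_f = None, np.inf
    bounds = [(-35.0, 35.0)] * 4  # keeps exp() finite during the search
    for v0 in starts:
        res = minimize(
            objective, v0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_v, best_f = res.x, res.fun
    if best_v is None:
        raise RuntimeError("Kriging fit failed: non-finite likelihood at every restart")
    return KrigingModel(
        X, y, KrigingHyperparams(np.exp(best_v[0]), np.exp(best_v[1:4])), nugget_rel=nugget_rel
    )


def kriging_predict(model: KrigingModel, params) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias of :meth:`KrigingModel.predict`."""
    return model.predict(params)
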