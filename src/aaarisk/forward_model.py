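"""Forward stress model: pressure protocol and a membrane-balloon solver.

The rupture framework only needs a map sigma_vm_max(t, alpha, beta) from
wall thickness and the two stiffness parameters to a peak von Mises stress
in kPa under an elevated-pressure protocol (mean arterial pressure raised by
50%).  Any callable honoring :class:`ForwardModel` can be plugged in — e.g.
an external finite-element solver reporting the 99th percentile of its
stress field.  The packaged stand-in is a statically determinate spherical
membrane ("balloon") with the aneurysm wall's hyperelastic strain-energy
density

    Psi(I1) = alpha (I1 - 3) + beta (I1 - 3)^2,

inflated equibiaxially: it exercises the real constitutive law, is smooth
in (t, alpha, beta), monotone decreasing in t, and evaluates in
microseconds, which is what surrogate training and Monte-Carlo estimation
need at desk scale.  It does not reproduce patient-specific finite-element
stresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MMHG_TO_KPA",
    "PressureProtocol",
    "WallParams",
    "ForwardModel",
    "MembraneBalloonModel",
    "LimitPointError",
    "mean_arterial_pressure",
    "balloon_stress",
]

MMHG_TO_KPA = 0.133322


class LimitPointError(RuntimeError):
    """Applied pressure exceeds the membrane's limit-point (snap-through) pressure."""

    def __init__(self, pressure_kpa: float, limit_kpa: float):
        super().__init__(
            f"applied pressure {pressure_kpa:.4g} kPa exceeds the inflation "
            f"limit pressure {limit_kpa:.4g} kPa (membrane instability)"
        )
        self.pressure_kpa = pressure_kpa
        self.limit_kpa = limit_kpa


@dataclass(frozen=True)
class PressureProtocol:
    """Blood-pressure protocol: systolic/diastolic [mmHg] and elevation factor."""

    systolic: float = 121.0
    diastolic: float = 87.0
    elevation_factor: float = 1.5

    def __post_init__(self) -> None:
        if not self.systolic >= self.diastolic > 0:
            raise ValueError("require systolic >= diastolic > 0")
        if self.elevation_factor < 0:
            raise ValueError("elevation_factor must be non-negative")

    def applied_pressure_kpa(self) -> float:
        """Elevated MAP converted to kPa."""
        return self.elevation_factor * mean_arterial_pressure(self) * MMHG_TO_KPA


@dataclass(frozen=True)
class WallParams:
    """theta = [t, alpha, beta]: thickness [mm] and stiffnesses [kPa]."""

    t: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("t", "alpha", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t, self.alpha, self.beta], dtype=float)


@runtime_checkable
class ForwardModel(Protocol):
    """Contract: evaluate(params) returns a positive peak stress in kPa.

    Field-valued solvers must apply their stress-summary statistic (the 99th
    percentile of the von Mises field) themselves; scalar models return their
    single stress.
    """

    def evaluate(self, params: WallParams) -> float:  # pragma: no cover - protocol
        ...


def mean_arterial_pressure(protocol: PressureProtocol) -> float:
    """MAP [mmHg] = systolic/3 + 2*diastolic/3."""
    return protocol.systolic / 3.0 + 2.0 * protocol.diastolic / 3.0


def _i1(lam: float) -> float:
    return 2.0 * lam**2 + lam**-4


def _w_prime(lam: float, alpha: float, beta: float) -> float:
    """d/d lambda of the equibiaxial strain-energy density."""
    e = _i1(lam) - 3.0
    return (alpha + 2.0 * beta * e) * (4.0 * lam - 4.0 * lam**-5)


@dataclass(frozen=True)
class MembraneBalloonModel:
    """Spherical membrane of reference radius R0 under the pressure protocol."""

    reference_radius: float = 25.0  # [mm]
    protocol: PressureProtocol = field(default_factory=PressureProtocol)

    def __post_init__(self) -> None:
        if self.reference_radius <= 0:
            raise ValueError("reference_radius must be positive")

    def pressure_of_stretch(self, lam: float, params: WallParams) -> float:
        """Inflation pressure [kPa] balancing an equibiaxial stretch lam."""
        return (params.t / self.reference_radius) * lam**-2 * _w_prime(lam, params.alpha, params.beta)

    def evaluate(self, params: WallParams) -> float:
        return balloon_stress(self, params)

    def __call__(self, params: WallParams) -> float:
        return self.evaluate(params)


def balloon_stress(
    model: MembraneBalloonModel, params: WallParams, lam_max: float = 10.0, n_scan: int = 4000
) -> float:
    """Wall stress [kPa] of the inflated membrane at the protocol pressure.

    Solves P = (t/R0) lam^-2 w'(lam) for the smallest root lam* >= 1 by
    bracketed root-finding (xtol 1e-10) and returns sigma = (lam*/2) w'(lam*).
    Raises :class:`LimitPointError` when the pressure exceeds the first local
    maximum of the pressure-stretch curve (possible for small beta).
    """
    p_target = model.protocol.applied_pressure_kpa()
    if p_target <= 0.0:
        return 0.0

    def p_of(lam: float) -> float:
        return model.pressure_of_stretch(lam, params)

    lams = np.geomspace(1.0, lam_max, n_scan)
    prev_lam, prev_p = 1.0, 0.0
    for lam in lams[1:]:
        p = p_of(lam)
        if p >= p_target:
            lo, hi = prev_lam, lam
            break
        if p < prev_p:  # pressure-stretch curve turned over before the target
            raise LimitPointError(p_target, prev_p)
        prev_lam, prev_p = lam, p
    else:
        raise LimitPointError(p_target, prev_p)

    lam_star = brentq(lambda l: p_of(l) - p_target, lo, hi, xtol=1e-10)
    return 0.5 * lam_star * _w_prime(lam_star, params.alpha, params.beta)
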