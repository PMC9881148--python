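"""Mass <-> diffusion-time calibration from globular size standards.

Globular proteins of known mass (SEC size standards) define an empirical
power law ``tau = alpha * M^beta`` between molecular mass and FCS diffusion
time.  For compact spheres ``tau ∝ r ∝ M^(1/3)``, so ``beta`` lands near 1/3;
solvation is absorbed into the empirical (alpha, beta).  The inverse,
``M = (tau/alpha)^(1/beta)``, gives a mass estimate for an unknown species —
an *upper bound* for non-spherical species, because any deviation from the
sphere lengthens the diffusion time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError


@dataclass(frozen=True)
class SizeStandard:
    """One calibration point: protein name, mass in kDa, diffusion time in s."""

    name: str
    mass: float
    tau_d: float

    def __post_init__(self):
        if self.mass <= 0 or self.tau_d <= 0:
            raise InvalidParameterError("mass and tau_d must be > 0")


@dataclass(frozen=True)
class SizeCalibration:
    """Fitted power law tau = alpha * mass^beta (tau in s, mass in kDa)."""

    alpha: float
    beta: float
    fit_residual: float = 0.0
    r_squared: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise InvalidParameterError("alpha must be > 0")
        if not (0 < self.beta < 1):
            raise InvalidParameterError("beta must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha_s_per_kDa_beta": self.alpha,
                "beta": self.beta,
                "fit_residual": self.fit_residual,
                "r_squared": self.r_squared,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SizeCalibration":
        d = json.loads(text)
        return cls(
            alpha=d["alpha_s_per_kDa_beta"],
            beta=d["beta"],
            fit_residual=d.get("fit_residual", 0.0),
            r_squared=d.get("r_squared", 1.0),
        )


def fit_size_calibration(standards: Sequence[SizeStandard]) -> SizeCalibration:
    """Least squares of log tau on log mass over >= 3 standards.

    Raises :class:`InsufficientDataError` with fewer than three standards;
    warns when the standards span less than a decade of mass (the exponent is
    then poorly constrained and extrapolation is risky).
    """
    if len(standards) < 3:
        raise InsufficientDataError("need >= 3 size standards")
    mass = np.array([s.mass for s in standards], dtype=float)
    tau = np.array([s.tau_d for s in standards], dtype=float)
    if mass.max() / mass.min() < 10.0 - 1e-9:
        warnings.warn(
            "size standards span less than one decade of mass; "
            "the fitted exponent is poorly constrained",
            stacklevel=2,
        )
    x, y = np.log(mass), np.log(tau)
    beta, loga = np.polyfit(x, y, 1)
    resid = y - (loga + beta * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SizeCalibration(
        alpha=float(np.exp(loga)), beta=float(beta), fit_residual=ss_res, r_squared=r2
    )


def tau_from_mass(mass: float, cal: SizeCalibration) -> float:
    """Sphere-equivalent diffusion time (s) predicted for a mass in kDa."""
    if mass <= 0:
        raise InvalidParameterError("mass must be > 0")
    return cal.alpha * mass**cal.beta


def mass_from_tau(tau: float, cal: SizeCalibration) -> float:
    """Mass (kDa) inferred from a diffusion time in s.

    Exact inverse of :func:`tau_from_mass`.  For species deviating from a
    sphere this is an upper bound on the true mass.
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    return (tau / cal.alpha) ** (1.0 / cal.beta)
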