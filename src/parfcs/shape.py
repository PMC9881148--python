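"""Prolate-ellipsoid translational diffusion (Perrin) and shape inversion.

A polymer chain that diffuses slower than the equal-volume sphere predicted
from its mass can be modelled as a prolate ellipsoid with short semiaxis ``a``
and long semiaxis ``b = a*H`` (aspect ratio ``H >= 1``).  Translational
friction parallel and perpendicular to the long axis is expressed through
effective radii of spheres with the same friction:

    r_par_eff  = (8a/3) [ -2H/(H^2-1)
                 + (2H^2-1)/(H^2-1)^(3/2) * ln((H+s)/(H-s)) ]^(-1)
    r_perp_eff = (8a/3) [  H/(H^2-1)
                 + (2H^2-3)/(H^2-1)^(3/2) * ln(H+s) ]^(-1)

with ``s = sqrt(H^2-1)``.  The orientation-averaged diffusion coefficient is

    D_ellipsoid = kB*T * [1/(3 f_par) + 2/(3 f_perp)],   f = 6 pi eta r_eff.

The shape factor ``T(H) = D_sphere / D_ellipsoid`` (equal-volume sphere of
radius ``a * H^(1/3)``) is dimensionless, equals 1 at H = 1, and increases
strictly with H, so the ratio of an experimental diffusion time to the
sphere-equivalent one inverts uniquely to an aspect ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import InvalidParameterError, InvalidShapeError

BOLTZMANN = 1.380649e-23  # J/K

#: Below 1 + this, the printed formulas are evaluated in their sphere limit
#: (both effective radii -> a) to avoid 0/0.
SPHERE_LIMIT_EPS = 1e-6

H_BRACKET = (1.0, 1000.0)


@dataclass(frozen=True)
class MediumConditions:
    """Solvent temperature (K) and dynamic viscosity (Pa s)."""

    temperature: float = 295.0
    viscosity: float = 9.54e-4  # water at ~22 degC

    def __post_init__(self):
        if self.temperature <= 0 or self.viscosity <= 0:
            raise InvalidParameterError("temperature and viscosity must be > 0")


@dataclass(frozen=True)
class EllipsoidShape:
    """Prolate ellipsoid: short semiaxis ``a`` (m) and aspect ratio ``H = b/a``."""

    a: float
    H: float

    def __post_init__(self):
        if self.a <= 0:
            raise InvalidParameterError("semiaxis a must be > 0")
        if self.H < 1:
            raise InvalidShapeError("oblate shapes (H < 1) are not supported")

    @property
    def b(self) -> float:
        return self.a * self.H

    @property
    def equivalent_sphere_radius(self) -> float:
        """Radius of the sphere with the same volume, a * H^(1/3)."""
        return self.a * self.H ** (1.0 / 3.0)

    @property
    def effective_radii(self):
        return perrin_effective_radii(self.a, self.H)


def perrin_effective_radii(a: float, H: float):
    """Effective hydrodynamic radii (r_par_eff, r_perp_eff) in units of ``a``'s.

    For ``H`` within ``SPHERE_LIMIT_EPS`` of 1 both radii return ``a`` (the
    sphere limit), where the closed forms are 0/0.
    """
    if a <= 0:
        raise InvalidParameterError("a must be > 0")
    if H < 1:
        raise InvalidShapeError("oblate shapes (H < 1) are not supported")
    if H < 1 + SPHERE_LIMIT_EPS:
        return a, a
    s = math.sqrt(H * H - 1.0)
    cube = (H * H - 1.0) ** 1.5
    r_par = (8.0 * a / 3.0) / (
        -2.0 * H / (H * H - 1.0)
        + (2.0 * H * H - 1.0) / cube * math.log((H + s) / (H - s))
    )
    r_perp = (8.0 * a / 3.0) / (
        H / (H * H - 1.0) + (2.0 * H * H - 3.0) / cube * math.log(H + s)
    )
    return r_par, r_perp


def ellipsoid_diffusion_coefficient(
    shape: EllipsoidShape, medium: MediumConditions = MediumConditions()
) -> float:
    """Orientation-averaged translational D of a prolate ellipsoid, cm^2/s.

    Never exceeds the equal-volume sphere's Stokes-Einstein value; equality
    holds only at H = 1.
    """
    r_par, r_perp = shape.effective_radii
    f_par = 6.0 * math.pi * medium.viscosity * r_par
    f_perp = 6.0 * math.pi * medium.viscosity * r_perp
    d_m2 = BOLTZMANN * medium.temperature * (1.0 / (3.0 * f_par) + 2.0 / (3.0 * f_perp))
    return d_m2 * 1e4


def shape_factor(H: float) -> float:
    """T(H) = tau_ellipsoid / tau_sphere = D_sphere / D_ellipsoid.

    Dimensionless, independent of the absolute size; T(1) = 1 and T increases
    strictly with H.
    """
    if H < 1:
        raise InvalidShapeError("H must be >= 1")
    if H < 1 + SPHERE_LIMIT_EPS:
        return 1.0
    r_par, r_perp = perrin_effective_radii(1.0, H)
    return 1.0 / (H ** (1.0 / 3.0) * (1.0 / (3.0 * r_par) + 2.0 / (3.0 * r_perp)))


def solve_aspect_ratio(tau_exp: float, tau_calc: float, rtol: float = 1e-10) -> float:
    """Invert T(H) = tau_exp / tau_calc for the aspect ratio H.

    ``tau_calc`` is the sphere-equivalent diffusion time from the mass
    calibration; ``tau_exp`` the measured one.  Monotone bracketed root search
    on H in [1, 1000].

    Raises
    ------
    InvalidShapeError
        tau_exp < tau_calc (faster than the equal-volume sphere: no prolate
        solution) or ratio beyond T(1000).
    """
    if tau_exp <= 0 or tau_calc <= 0:
        raise InvalidParameterError("diffusion times must be > 0")
    ratio = tau_exp / tau_calc
    if ratio < 1.0:
        raise InvalidShapeError(
            f"tau_exp/tau_calc = {ratio:.4f} < 1: no prolate solution"
        )
    if ratio == 1.0 or ratio - 1.0 < 1e-12:
        return 1.0
    lo, hi = H_BRACKET
    if ratio > shape_factor(hi):
        raise InvalidShapeError(f"ratio {ratio:.3f} beyond T({hi:g})")
    # root of T(H) - ratio on log H; T strictly increasing => unique
    root = brentq(
        lambda logh: shape_factor(math.exp(logh)) - ratio,
        math.log(1.0 + SPHERE_LIMIT_EPS),
        math.log(hi),
        xtol=1e-14,
        rtol=8.9e-16,
    )
    H = math.exp(root)
    assert abs(shape_factor(H) - ratio) <= rtol * ratio
    return H
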