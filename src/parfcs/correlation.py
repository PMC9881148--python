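"""Autocorrelation model for free 3D diffusion through a Gaussian confocal focus.

The normalised intensity autocorrelation of a single freely diffusing species
crossing a 3D Gaussian detection volume decays as

    g2(tau) = g0 / [(1 + tau/tau_d) * sqrt(1 + tau/(tau_d * kappa**2))]

where ``g0`` is the zero-lag amplitude (inverse mean occupancy of the focus),
``tau_d`` the diffusion time, and ``kappa`` the axial-to-lateral aspect ratio
of the focus.  The diffusion time relates to the diffusion coefficient through
``D = omega_xy**2 / (4 * tau_d)`` with ``omega_xy`` the lateral 1/e^2 radius.

Triplet/photophysics terms are deliberately omitted: fits are restricted to a
lag window (default 0.1 ms - 1 s) that excludes those fast processes.

Units: seconds and metres internally; readers/writers convert from µs/nm at
the file boundary (see :mod:`parfcs.io`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import lmfit
import numpy as np

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InsufficientSignalError,
    InvalidParameterError,
)

AVOGADRO = 6.02214076e23  # 1/mol

DEFAULT_FIT_WINDOW = (1e-4, 1.0)  # seconds


@dataclass(frozen=True)
class CorrelationCurve:
    """One measured (or simulated) autocorrelation curve.

    Parameters
    ----------
    lags : array of float
        Lag times in seconds, strictly increasing, all > 0.
    values : array of float
        Excess correlation amplitudes g2(tau) (dimensionless).
    sd : array of float, optional
        Per-lag standard deviations (> 0), used as weights when fitting.
    meta : str
        Free-text provenance.
    """

    lags: np.ndarray
    values: np.ndarray
    sd: Optional[np.ndarray] = None
    meta: str = ""

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.ndim != 1 or values.shape != lags.shape:
            raise InvalidParameterError("lags and values must be 1-D and equal length")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise InvalidParameterError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("correlation values must be finite")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
            if sd.shape != lags.shape or np.any(sd <= 0):
                raise InvalidParameterError("sd must be positive and match lags")

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class FocusGeometry:
    """Calibrated confocal detection volume.

    ``omega_xy`` is the lateral 1/e^2 radius in metres, ``kappa`` the axial
    elongation; the effective volume is ``v_eff = pi^(3/2) omega_xy^3 kappa``
    (litres), the volume relating the zero-lag amplitude to concentration.
    """

    omega_xy: float
    kappa: float

    def __post_init__(self):
        if self.omega_xy <= 0:
            raise InvalidParameterError("omega_xy must be > 0")
        if self.kappa < 1:
            raise InvalidParameterError("kappa must be >= 1")

    @property
    def v_eff(self) -> float:
        """Effective detection volume in litres."""
        return math.pi ** 1.5 * self.omega_xy ** 3 * self.kappa * 1e3


@dataclass(frozen=True)
class FCSFitResult:
    """Least-squares estimates for one correlation curve."""

    g0: float
    tau_d: float
    kappa: float
    residual_chi2: float
    covariance: Optional[np.ndarray]
    fit_window: Tuple[float, float]
    param_names: Tuple[str, ...] = field(default=("g0", "tau_d"))
    kappa_fixed: bool = True
    n_points: int = 0


def model_g2(lag, g0: float, tau_d: float, kappa: float):
    """Evaluate the 3D-Gaussian-focus diffusion autocorrelation.

    Monotonically non-increasing in ``lag``; tends to ``g0`` as lag -> 0 and
    to 0 as lag -> infinity.  ``lag`` may be a scalar or array (seconds).
    """
    if g0 <= 0:
        raise InvalidParameterError("g0 must be > 0")
    if tau_d <= 0:
        raise InvalidParameterError("tau_d must be > 0")
    if kappa < 1:
        raise InvalidParameterError("kappa must be >= 1")
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise InvalidParameterError("lag must be >= 0")
    x = lag / tau_d
    out = g0 / ((1.0 + x) * np.sqrt(1.0 + x / kappa ** 2))
    return out if out.ndim else float(out)


def fit_g2(
    curve: CorrelationCurve,
    kappa: Optional[float] = None,
    window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
    min_points: int = 8,
) -> FCSFitResult:
    """Fit the diffusion model to a correlation curve.

    Parameters
    ----------
    curve : CorrelationCurve
    kappa : float, optional
        Fix the focus aspect ratio to this value (the daily-calibration
        convention: kappa is fitted once on the reference-dye curve, then held
        fixed for sample fits).  ``None`` lets kappa float.
    window : (float, float)
        Lag window in seconds; points outside are ignored.  The default
        excludes sub-0.1 ms lags where photophysics would contaminate the
        diffusion term.

    Returns
    -------
    FCSFitResult

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` lags inside the window.
    InsufficientSignalError
        The curve carries no resolvable amplitude.
    FitFailureError
        The optimiser did not converge (carries the last iterate).
    """
    lo, hi = window
    if not (0 < lo < hi):
        raise InvalidParameterError("window must satisfy 0 < lo < hi")
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    lags = curve.lags[mask]
    vals = curve.values[mask]
    sd = curve.sd[mask] if curve.sd is not None else None
    if lags.size < min_points:
        raise InsufficientDataError(
            f"only {lags.size} points inside window {window}; need >= {min_points}"
        )

    peak = float(np.max(vals)) if vals.size else 0.0
    noise = float(np.std(np.diff(vals)) / math.sqrt(2)) if vals.size > 2 else 0.0
    if peak <= 1e-10 or (noise > 0 and peak < 3 * noise):
        raise InsufficientSignalError("correlation amplitude indistinguishable from zero")

    params = lmfit.Parameters()
    params.add("g0", value=peak, min=1e-12)
    # crude initial tau_d: lag where the curve first drops below half the peak
    below = lags[vals < 0.5 * peak]
    tau0 = float(below[0]) if below.size else float(lags[lags.size // 2])
    params.add("tau_d", value=tau0, min=lo * 1e-3, max=hi * 1e3)
    if kappa is None:
        params.add("kappa", value=5.0, min=1.0, max=100.0)
    else:
        if kappa < 1:
            raise InvalidParameterError("fixed kappa must be >= 1")
        params.add("kappa", value=float(kappa), vary=False)

    weights = 1.0 / sd if sd is not None else None

    def residual(p):
        m = model_g2(lags, p["g0"].value, p["tau_d"].value, p["kappa"].value)
        r = vals - m
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    if not result.success:
        raise FitFailureError(
            f"fit did not converge: {result.message}",
            last_iterate={k: v.value for k, v in result.params.items()},
        )
    p = result.params
    varied = tuple(name for name in p if p[name].vary)
    cov = result.covar if result.covar is not None else None
    return FCSFitResult(
        g0=p["g0"].value,
        tau_d=p["tau_d"].value,
        kappa=p["kappa"].value,
        residual_chi2=float(result.chisqr),
        covariance=cov,
        fit_window=window,
        param_names=varied,
        kappa_fixed=kappa is not None,
        n_points=int(lags.size),
    )


def calibrate_focus(tau_d_ref: float, d_ref: float, kappa: float = 5.0) -> FocusGeometry:
    """Derive the focus geometry from a reference-dye measurement.

    ``tau_d_ref`` is the fitted diffusion time (s) of a dye of known diffusion
    coefficient ``d_ref`` (cm^2/s); the lateral radius follows from
    ``omega_xy = sqrt(4 D tau_d)``.  ``kappa`` is taken from the reference fit.
    """
    if tau_d_ref <= 0 or d_ref <= 0:
        raise InvalidParameterError("tau_d_ref and d_ref must be > 0")
    omega_cm = math.sqrt(4.0 * d_ref * tau_d_ref)
    return FocusGeometry(omega_xy=omega_cm * 1e-2, kappa=kappa)


def diffusion_coefficient(tau_d: float, focus: FocusGeometry) -> float:
    """Diffusion coefficient D = omega_xy^2 / (4 tau_d), in cm^2/s."""
    if tau_d <= 0:
        raise InvalidParameterError("tau_d must be > 0")
    omega_cm = focus.omega_xy * 1e2
    return omega_cm ** 2 / (4.0 * tau_d)


def labelling_efficiency(g0: float, focus: FocusGeometry, total_conc: float) -> float:
    """Fraction of chains carrying a dye, from the zero-lag amplitude.

    The amplitude is inversely proportional to the labelled-species
    concentration: ``c_lab = 1 / (g0 * v_eff * N_A)``.  Relating ``c_lab`` to
    the total chain concentration gives the labelling efficiency.  No
    background correction is applied to ``g0``; a value > 1 is reported as is,
    with a warning (uncorrected amplitudes can overestimate c_lab).
    """
    if g0 <= 0 or total_conc <= 0:
        raise InvalidParameterError("g0 and total_conc must be > 0")
    c_lab = 1.0 / (g0 * focus.v_eff * AVOGADRO)  # mol/L
    eff = c_lab / total_conc
    if eff > 1:
        warnings.warn(
            f"labelling efficiency {eff:.3f} > 1; amplitude not background-corrected",
            stacklevel=2,
        )
    return eff
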