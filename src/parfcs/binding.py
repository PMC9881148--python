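"""Binding curves, Kd estimation and stoichiometry from diffusion-time titrations.

A fixed, labelled probe (PAR chain or DNA oligonucleotide, typically 10 nM) is
titrated with increasing protein.  Binding slows diffusion, so the apparent
diffusion time rises with protein concentration.  Under a two-state 1:1
apparent-tau model with protein in excess over probe:

    tau(c) = tau_free + (tau_bound - tau_free) * c / (c + Kd)

The apparent tau of the free/bound mixture is modelled as the
fraction-weighted mean; the true FCS observable is amplitude/brightness
weighted, a documented approximation (the synthetic generator can emit either
convention to quantify the bias, see :mod:`parfcs.simulate`).

A Kd is only reported when the titration actually reaches a plateau inside
the fit window; otherwise the fit is flagged not-estimable and the fitted
value is at best a lower bound.  Multi-phase curves (a second rise at high
concentration) are handled by restricting the window to the first binding
event, not by a multi-site model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, curve_fit

from .calibration import SizeCalibration, mass_from_tau, tau_from_mass
from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

#: tau(c_max) must reach this fraction of saturation for a Kd to be reported,
#: i.e. kd <= c_max/4.
PLATEAU_SATURATION = 0.8

CHI2_95 = 3.841458820694124  # chi2.ppf(0.95, df=1)


@dataclass(frozen=True)
class TitrationSeries:
    """Protein concentration vs observed diffusion time (mean ± SD).

    Concentrations are total protein in mol/L and must include a zero
    ("probe only") point; ``probe_conc`` is the fixed labelled-species
    concentration.
    """

    concentrations: np.ndarray  # mol/L
    tau_mean: np.ndarray  # s
    tau_sd: Optional[np.ndarray] = None  # s
    probe_conc: float = 10e-9
    replicates: int = 1
    meta: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        t = np.asarray(self.tau_mean, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "tau_mean", t)
        if c.shape != t.shape or c.ndim != 1:
            raise InvalidParameterError("concentrations and tau_mean must match")
        if np.any(c < 0) or np.any(t <= 0):
            raise InvalidParameterError("concentrations >= 0 and tau_mean > 0 required")
        if not np.any(c == 0):
            raise InvalidParameterError("series must include a zero/'probe only' point")
        if self.probe_conc <= 0:
            raise InvalidParameterError("probe_conc must be > 0")
        if self.tau_sd is not None:
            sd = np.asarray(self.tau_sd, dtype=float)
            object.__setattr__(self, "tau_sd", sd)
            if sd.shape != c.shape or np.any(sd <= 0):
                raise InvalidParameterError("tau_sd must be positive and match shape")

    def __len__(self) -> int:
        return self.concentrations.size


@dataclass(frozen=True)
class BindingFit:
    """Result of a windowed two-state fit.

    ``estimable`` is False when no plateau was reached inside the window; then
    ``kd`` is the best-fit value but only a lower bound is defensible.
    """

    kd: float  # mol/L
    tau_free: float  # s
    tau_bound: float  # s
    window: Tuple[float, float]
    ci: Tuple[float, float]  # 95% profile-likelihood CI on kd
    estimable: bool
    chi2: float
    n_points: int


@dataclass(frozen=True)
class StoichiometryEstimate:
    """Bound proteins per probe chain, from the complex's apparent mass.

    ``is_upper_bound`` is always True: non-sphericity inflates the apparent
    mass, so ``n_bound`` is an 'at least / at most' style bound, and
    ``n_bound_floor`` rounds down to the defensible integer count.
    """

    n_bound: float
    complex_mass: float  # kDa
    is_upper_bound: bool = True

    @property
    def n_bound_floor(self) -> int:
        return int(math.floor(self.n_bound + 1e-9))  # tolerate roundoff at integers


def binding_model_tau(conc, kd: float, tau_free: float, tau_bound: float):
    """Apparent diffusion time of the probe at total protein concentration c.

    Monotone increasing in c; tau(0) = tau_free, tau(inf) = tau_bound,
    tau(Kd) = midpoint.
    """
    if kd <= 0 or tau_free <= 0 or tau_bound <= 0:
        raise InvalidParameterError("kd, tau_free, tau_bound must be > 0")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentration must be >= 0")
    out = tau_free + (tau_bound - tau_free) * conc / (conc + kd)
    return out if out.ndim else float(out)


def _chi2(series_c, series_t, w, kd, tf, tb):
    r = (series_t - binding_model_tau(series_c, kd, tf, tb)) * w
    return float(np.sum(r * r))


def fit_kd(
    series: TitrationSeries,
    window: Optional[Tuple[float, float]] = None,
    compute_ci: bool = True,
) -> BindingFit:
    """Weighted least-squares fit of the two-state model on a window.

    Parameters
    ----------
    series : TitrationSeries
    window : (float, float), optional
        Concentration range (mol/L) to fit; zero is always kept.  Use this to
        isolate the first binding event of a multi-phase curve.
    compute_ci : bool
        Profile-likelihood 95% CI on Kd (a handful of constrained refits).

    Returns
    -------
    BindingFit
        With ``estimable=False`` when no plateau is reached in-window (the
        fitted Kd exceeds c_max/4, i.e. < 80% saturation at the top point).
    """
    c_all, t_all = series.concentrations, series.tau_mean
    sd_all = series.tau_sd
    if window is None:
        mask = np.ones_like(c_all, dtype=bool)
        window = (0.0, float(c_all.max()))
    else:
        lo, hi = window
        mask = ((c_all >= lo) & (c_all <= hi)) | (c_all == 0)
    c, t = c_all[mask], t_all[mask]
    w = 1.0 / sd_all[mask] if sd_all is not None else np.ones_like(c)
    if c.size < 5:
        raise InsufficientDataError(f"only {c.size} points in window; need >= 5")

    c_max = float(c.max())
    tf0 = float(t[c == 0].mean())
    tb0 = float(t.max())
    if tb0 <= tf0:
        tb0 = tf0 * 1.5
    kd0 = c_max / 10.0

    def model(x, log_kd, tf, tb):
        return binding_model_tau(x, math.exp(log_kd), tf, tb)

    try:
        popt, _ = curve_fit(
            model,
            c,
            t,
            p0=[math.log(kd0), tf0, tb0],
            sigma=1.0 / w,
            absolute_sigma=sd_all is not None,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitFailureError(f"Kd fit did not converge: {exc}") from exc
    kd_hat, tf_hat, tb_hat = math.exp(popt[0]), float(popt[1]), float(popt[2])
    chi2_min = _chi2(c, t, w, kd_hat, tf_hat, tb_hat)
    estimable = kd_hat <= c_max * (1.0 - PLATEAU_SATURATION) / PLATEAU_SATURATION
    estimable = estimable and tb_hat > tf_hat
    # a monotone rise that never saturates can masquerade as an isotherm with
    # small kd; reject fits the two-state model does not actually describe
    if estimable:
        if sd_all is not None:
            chi2_red = chi2_min / max(c.size - 3, 1)
            estimable = chi2_red < 10.0
        else:
            model_t = binding_model_tau(c, kd_hat, tf_hat, tb_hat)
            rel_dev = float(np.max(np.abs(model_t - t))) / max(tb_hat - tf_hat, 1e-30)
            estimable = rel_dev < 0.05
    estimable = bool(estimable)

    ci = (float("nan"), float("nan"))
    if compute_ci and estimable:
        ci = _profile_ci_kd(c, t, w, kd_hat, chi2_min)
    return BindingFit(
        kd=kd_hat,
        tau_free=tf_hat,
        tau_bound=tb_hat,
        window=window,
        ci=ci,
        estimable=estimable,
        chi2=chi2_min,
        n_points=int(c.size),
    )


def _profile_chi2(c, t, w, kd):
    """Minimum chi2 over (tau_free, tau_bound) at fixed kd (linear solve)."""
    # model is linear in (tf, tb): tau = tf*(1-f) + tb*f with f = c/(c+kd)
    f = c / (c + kd)
    A = np.column_stack([(1.0 - f) * w, f * w])
    coef, *_ = np.linalg.lstsq(A, t * w, rcond=None)
    r = t * w - A @ coef
    return float(np.sum(r * r))


def _profile_ci_kd(c, t, w, kd_hat, chi2_min):
    """95% profile-likelihood interval on Kd via bisection on delta-chi2."""
    target = chi2_min + CHI2_95

    def g(log_kd):
        return _profile_chi2(c, t, w, math.exp(log_kd)) - target

    log_kd = math.log(kd_hat)
    lo = log_kd
    step = 0.5
    for _ in range(60):
        if g(lo - step) > 0:
            break
        lo -= step
    else:  # pragma: no cover
        return (0.0, float("inf"))
    lower = math.exp(brentq(g, lo - step, log_kd, xtol=1e-10)) if g(log_kd) < 0 else kd_hat
    hi = log_kd
    for _ in range(60):
        if g(hi + step) > 0:
            break
        hi += step
    else:
        return (lower, float("inf"))
    upper = math.exp(brentq(g, log_kd, hi + step, xtol=1e-10)) if g(log_kd) < 0 else kd_hat
    return (lower, upper)


def detect_onset(
    series: TitrationSeries, z: float = 3.0, abs_threshold: Optional[float] = None
) -> Optional[float]:
    """Smallest concentration whose tau exceeds the probe-only tau significantly.

    The threshold is ``z * sd`` of the zero point; when the series carries no
    SDs an explicit ``abs_threshold`` (seconds) is required.  Returns ``None``
    when no concentration crosses the threshold.
    """
    c, t = series.concentrations, series.tau_mean
    zero_mask = c == 0
    tau_free = float(t[zero_mask].mean())
    if series.tau_sd is not None:
        thresh = z * float(series.tau_sd[zero_mask].mean())
    elif abs_threshold is not None:
        thresh = abs_threshold
    else:
        raise InvalidParameterError("series has no sd; supply abs_threshold")
    nz = ~zero_mask
    exceeding = c[nz][t[nz] > tau_free + thresh]
    return float(exceeding.min()) if exceeding.size else None


def estimate_stoichiometry(
    tau_complex: float,
    cal: SizeCalibration,
    probe_mass: float,
    unit_mass: float,
) -> StoichiometryEstimate:
    """Bound proteins per probe from the complex's sphere-equivalent mass.

    ``unit_mass`` is the mass of one binding unit (e.g. ~176 kDa for a p53
    tetramer of 4 x 44 kDa).  The complex mass from the calibration is an
    upper bound for non-spherical complexes, hence ``is_upper_bound``.
    A ``tau_complex`` below the probe's own predicted tau yields n_bound = 0
    with a warning.
    """
    if unit_mass <= 0 or probe_mass <= 0:
        raise InvalidParameterError("unit_mass and probe_mass must be > 0")
    if tau_complex <= 0:
        raise InvalidParameterError("tau_complex must be > 0")
    tau_probe = tau_from_mass(probe_mass, cal)
    if tau_complex < tau_probe:
        warnings.warn(
            "tau_complex below the probe's own diffusion time; n_bound = 0",
            stacklevel=2,
        )
        return StoichiometryEstimate(n_bound=0.0, complex_mass=probe_mass)
    complex_mass = mass_from_tau(tau_complex, cal)
    n = max(0.0, (complex_mass - probe_mass) / unit_mass)
    return StoichiometryEstimate(n_bound=n, complex_mass=complex_mass)
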