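"""Photon counting histogram (PCH) models and labelled-chain combinatorics.

Two independent pieces of evidence identify multi-chain complexes:

1. **Photon statistics.**  The distribution of photon counts per fixed time
   bin (default 40 µs) resolves species by molecular brightness.  For
   particles Poisson-distributed in space and a 3D Gaussian detection profile
   ``B(r) = exp(-2 rho^2/w^2 - 2 z^2/(kappa w)^2)``, the total count per bin
   is compound-Poisson.  Writing the per-particle emission as Poisson with
   mean ``q B(r)``, the count distribution has cluster rates

       chi_j = n_mean / sqrt(2 pi) * Int_0^inf sqrt(t) Pois(j; q e^-t) dt

   (``n_mean`` = mean occupancy of the effective volume pi^(3/2) w^3 kappa,
   ``q`` = brightness in counts/bin/molecule), evaluated with the t = u^2
   substitution and composite Gauss-Legendre quadrature, and the histogram
   follows from the compound-Poisson (Panjer) recursion.  Independent species
   convolve, i.e. their cluster rates add.  The mean count per bin is
   ``sum n_mean * q * GAMMA_3DG`` with the 3D-Gaussian focus factor
   ``GAMMA_3DG = 2^(-3/2)``.

2. **Labelling combinatorics.**  Chains carry at most one terminal dye with
   probability ``L``.  For a complex of ``P`` chains the number of dyes is
   Binomial(P, L); the fractions of singly labelled (N1) and multiply
   labelled (Nm) complexes, and the probability-weighted multi-label
   brightness (qm, in units of the single-dye brightness), vary with P in a
   way that lets the observed N1/Nm and qm/q1 ratios be inverted for the
   integer number of chains per complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InvalidParameterError,
    TruncationError,
)

#: First moment of the 3D Gaussian profile: <B> over the effective volume.
GAMMA_3DG = 2.0 ** -1.5


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PCHistogram:
    """Photon-count frequency table at fixed bin time."""

    counts_axis: np.ndarray  # photon counts per bin, non-negative ints
    frequency: np.ndarray  # occurrences
    bin_time: float = 40e-6  # s
    duration: float = 300.0  # s

    def __post_init__(self):
        k = np.asarray(self.counts_axis, dtype=int)
        f = np.asarray(self.frequency, dtype=float)
        object.__setattr__(self, "counts_axis", k)
        object.__setattr__(self, "frequency", f)
        if k.shape != f.shape or k.ndim != 1:
            raise InvalidParameterError("counts_axis and frequency must match")
        if np.any(k < 0) or np.any(f < 0):
            raise InvalidParameterError("counts and frequencies must be >= 0")
        if self.bin_time <= 0 or self.duration <= 0:
            raise InvalidParameterError("bin_time and duration must be > 0")
        if f.sum() * self.bin_time > self.duration * (1 + 1e-9):
            raise InvalidParameterError("more bins than fit into the duration")

    @property
    def n_events(self) -> float:
        return float(self.frequency.sum())

    def dense(self, max_count: Optional[int] = None) -> np.ndarray:
        """Frequencies on a dense 0..max_count axis."""
        kmax = int(max_count if max_count is not None else self.counts_axis.max())
        out = np.zeros(kmax + 1)
        for k, f in zip(self.counts_axis, self.frequency):
            if k <= kmax:
                out[k] += f
        return out


@dataclass(frozen=True)
class SpeciesBrightness:
    """One brightness species: mean focus occupancy and counts/bin/molecule."""

    n_mean: float
    q: float

    def __post_init__(self):
        if self.n_mean <= 0 or self.q <= 0:
            raise InvalidParameterError("n_mean and q must be > 0")


@dataclass(frozen=True)
class LabelledComplexModel:
    """Complex of P chains, each independently labelled with probability L."""

    L: float
    P: int

    def __post_init__(self):
        if not (0 < self.L < 1):
            raise InvalidParameterError("L must lie in (0, 1)")
        if self.P < 1:
            raise InvalidParameterError("P must be >= 1")


# --------------------------------------------------------------------------
# labelling combinatorics
# --------------------------------------------------------------------------


def _check_PL(P: int, L: float):
    if P < 1 or int(P) != P:
        raise InvalidParameterError("P must be a positive integer")
    if not (0 < L < 1):
        raise InvalidParameterError("L must lie in (0, 1)")


def p_x_labels(P: int, x: int, L: float) -> float:
    """Probability that a complex of P chains carries exactly x dyes.

    Binomial pmf: L^x (1-L)^(P-x) C(P, x); sums to 1 over x = 0..P.
    """
    _check_PL(P, L)
    if x < 0 or x > P:
        raise InvalidParameterError("x must satisfy 0 <= x <= P")
    log_c = gammaln(P + 1) - gammaln(x + 1) - gammaln(P - x + 1)
    return float(math.exp(log_c + x * math.log(L) + (P - x) * math.log1p(-L)))


def p_single_label(P: int, L: float) -> float:
    """N1(P) = L (1-L)^(P-1) P — exactly one dye in the complex."""
    _check_PL(P, L)
    return float(L * (1.0 - L) ** (P - 1) * P)


def p_multi_label(P: int, L: float) -> float:
    """Nm(P) = 1 - (1-L)^P - N1(P) — more than one dye in the complex."""
    _check_PL(P, L)
    if P == 1:
        return 0.0  # a single chain cannot carry two dyes; avoids 1-(1-L)-L roundoff
    return float(max(0.0, 1.0 - (1.0 - L) ** P - p_single_label(P, L)))


def mean_multi_brightness(P: int, L: float) -> float:
    """qm(P) = sum_{x>=2} x Nx(P), in units of the single-dye brightness.

    This is the probability-weighted *unconditional* sum (equal to
    L*P - N1(P), the binomial mean minus the singly-labelled term), not the
    mean brightness conditional on being multiply labelled — see
    :func:`mean_multi_brightness_conditional` for that variant.
    """
    _check_PL(P, L)
    return float(L * P - p_single_label(P, L))


def mean_multi_brightness_conditional(P: int, L: float) -> float:
    """Mean dyes per complex *given* it is multiply labelled: qm / Nm."""
    nm = p_multi_label(P, L)
    if nm == 0:
        return 0.0
    return mean_multi_brightness(P, L) / nm


def solve_chains_per_complex(
    singly: SpeciesBrightness,
    multiply: Optional[SpeciesBrightness],
    L: float,
    p_max: int = 100,
) -> Tuple[int, dict]:
    """Integer number of PAR chains per complex from observed species ratios.

    Compares the observed number ratio N1/Nm and brightness ratio qm/q1
    against the combinatorial predictions, minimising the summed squared log
    error over P in [1, p_max]; ties break toward smaller P.

    Returns ``(P, diagnostics)`` where diagnostics carries per-ratio
    residuals.  A vanishing multiply-labelled population returns P = 1 with a
    ``degenerate`` flag.
    """
    if not (0 < L < 1):
        raise InvalidParameterError("L must lie in (0, 1)")
    if multiply is None or multiply.n_mean < 1e-12 * singly.n_mean:
        return 1, {"degenerate": True, "residual": 0.0}
    obs_num = singly.n_mean / multiply.n_mean
    obs_bright = multiply.q / singly.q
    best_p, best_loss, best_res = 1, float("inf"), (0.0, 0.0)
    for P in range(1, p_max + 1):
        nm = p_multi_label(P, L)
        if nm <= 0:  # P = 1: no multiply labelled complexes possible
            continue
        mod_num = p_single_label(P, L) / nm
        mod_bright = mean_multi_brightness(P, L)
        r1 = math.log(obs_num / mod_num)
        r2 = math.log(obs_bright / mod_bright)
        loss = r1 * r1 + r2 * r2
        if loss < best_loss - 1e-15:
            best_p, best_loss, best_res = P, loss, (r1, r2)
    return best_p, {
        "degenerate": False,
        "residual": best_loss,
        "log_residual_number_ratio": best_res[0],
        "log_residual_brightness_ratio": best_res[1],
    }


# --------------------------------------------------------------------------
# PCH model
# --------------------------------------------------------------------------

_GAUSS_X, _GAUSS_W = np.polynomial.legendre.leggauss(24)


def _cluster_rates(
    n_mean: float,
    q: float,
    max_count: int,
    focus_correction: float = 0.0,
    u_max: float = 9.0,
    n_panels: int = 24,
) -> np.ndarray:
    """chi_j for j = 1..max_count via composite Gauss-Legendre on t = u^2.

    ``focus_correction`` F perturbs the volume-vs-intensity weight first
    order, sqrt(t) -> sqrt(t) (1 + F t), modelling out-of-focus deviation of
    the detection profile from the ideal 3D Gaussian (F = 0: ideal).
    """
    edges = np.linspace(0.0, u_max, n_panels + 1)
    half = 0.5 * np.diff(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    u = (half[:, None] * _GAUSS_X[None, :] + mid[:, None]).ravel()
    wu = (half[:, None] * _GAUSS_W[None, :]).ravel()
    t = u * u
    j = np.arange(1, max_count + 1)[:, None]
    lam = q * np.exp(-t)[None, :]
    logp = j * np.log(lam) - lam - gammaln(j + 1)
    weight = 2.0 * u * u * (1.0 + focus_correction * t)
    integ = (weight[None, :] * np.exp(logp) * wu[None, :]).sum(axis=1)
    return n_mean / math.sqrt(2.0 * math.pi) * integ


def pch_model(
    species: Sequence[SpeciesBrightness],
    max_count: int,
    focus_correction: float = 0.0,
    afterpulse_prob: float = 0.0,
    truncation_tol: float = 1e-6,
) -> np.ndarray:
    """Photon-count probabilities P(0..max_count) for a species mixture.

    Independent species convolve, which in the compound-Poisson picture means
    their cluster rates add; the distribution follows from the Panjer
    recursion and is exact on 0..max_count (the recursion never references
    truncated entries).  If the mass beyond ``max_count`` exceeds
    ``truncation_tol`` a :class:`TruncationError` asks for a wider axis.

    ``afterpulse_prob`` models detector afterpulsing as an independent chance
    of one extra count per detected count (count k -> k + Binomial(k, p)).
    """
    if not species:
        raise InvalidParameterError("need at least one species")
    if max_count < 1:
        raise InvalidParameterError("max_count must be >= 1")
    if not (0 <= afterpulse_prob < 1):
        raise InvalidParameterError("afterpulse_prob must lie in [0, 1)")
    chi = np.zeros(max_count + 1)  # chi[j], chi[0] unused
    for sp in species:
        chi[1:] += _cluster_rates(sp.n_mean, sp.q, max_count, focus_correction)
    probs = np.zeros(max_count + 1)
    probs[0] = math.exp(-chi[1:].sum())
    jchi = np.arange(max_count + 1) * chi
    for k in range(1, max_count + 1):
        probs[k] = np.dot(jchi[1 : k + 1], probs[k - 1 :: -1][:k]) / k
    if afterpulse_prob > 0:
        probs = _apply_afterpulse(probs, afterpulse_prob, max_count)
    remainder = 1.0 - probs.sum()
    if remainder > truncation_tol:
        raise TruncationError(
            f"{remainder:.2e} probability beyond max_count={max_count}; widen it"
        )
    return probs


def _apply_afterpulse(probs: np.ndarray, p: float, max_count: int) -> np.ndarray:
    """Redistribute k true counts to k + Binomial(k, p) observed counts."""
    out = np.zeros_like(probs)
    for k in range(probs.size):
        if probs[k] == 0:
            continue
        for extra in range(k + 1):
            kk = k + extra
            if kk > max_count:
                break
            log_c = gammaln(k + 1) - gammaln(extra + 1) - gammaln(k - extra + 1)
            out[kk] += probs[k] * math.exp(
                log_c + extra * math.log(p) + (k - extra) * math.log1p(-p)
            )
    return out


def pch_mean(species: Sequence[SpeciesBrightness]) -> float:
    """Analytic mean count per bin: sum n_mean * q * GAMMA_3DG."""
    return float(sum(sp.n_mean * sp.q for sp in species) * GAMMA_3DG)


@dataclass(frozen=True)
class PCHFitResult:
    """Maximum-likelihood PCH fit for one or two brightness species."""

    species: Tuple[SpeciesBrightness, ...]
    reduced_chi2: float
    log_likelihood: float
    n_species: int
    focus_correction: float
    afterpulse_prob: float


def fit_pch(
    hist: PCHistogram,
    n_species: int = 1,
    afterpulse: bool = False,
    focus_correction: float = 0.0,
) -> PCHFitResult:
    """Fit a 1- or 2-species PCH model by multinomial maximum likelihood.

    The reported reduced chi-square, computed on bins with appreciable
    expected occupancy, is the statistic used to compare one- against
    two-species models.  Afterpulsing, when enabled, adds one fitted
    probability of an extra count per detected count.
    """
    if n_species not in (1, 2):
        raise InvalidParameterError("n_species must be 1 or 2")
    freq = hist.dense()
    n_bins = freq.sum()
    if n_bins == 0 or (freq[1:].sum() == 0):
        raise DegenerateInputError("histogram carries no photon counts")
    kmax = freq.size - 1
    max_count = max(kmax + 10, int(kmax * 1.5))
    ks = np.arange(freq.size)
    mean = float((ks * freq).sum() / n_bins)

    # moment-based start: one species at q ~ mean/occupancy guess
    starts: List[np.ndarray]
    if n_species == 1:
        starts = [np.log([1.0, max(mean, 0.05) / GAMMA_3DG])]
    else:
        m = max(mean, 0.05) / GAMMA_3DG
        starts = [
            np.log([1.0, 0.7 * m, 0.1, 4.0 * m]),
            np.log([2.0, 0.5 * m, 0.05, 8.0 * m]),
        ]
    if afterpulse:
        starts = [np.append(s, math.log(0.01)) for s in starts]

    def unpack(theta):
        vals = np.exp(theta)
        ap = vals[-1] if afterpulse else 0.0
        core = vals[:-1] if afterpulse else vals
        sp = tuple(
            SpeciesBrightness(core[2 * i], core[2 * i + 1]) for i in range(n_species)
        )
        return sp, min(ap, 0.5)

    def nll(theta):
        try:
            sp, ap = unpack(theta)
            probs = pch_model(
                sp, max_count, focus_correction, ap, truncation_tol=1e-4
            )[: freq.size]
        except (InvalidParameterError, TruncationError, OverflowError):
            return 1e12
        probs = np.clip(probs, 1e-300, None)
        return -float(np.dot(freq, np.log(probs)))

    best = None
    for s0 in starts:
        res = minimize(nll, s0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 8000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("PCH fit failed", last_iterate=best)
    sp, ap = unpack(best.x)
    probs = pch_model(sp, max_count, focus_correction, ap, truncation_tol=1e-4)[
        : freq.size
    ]
    expected = probs * n_bins
    use = expected > 1e-2
    chi2 = float(np.sum((freq[use] - expected[use]) ** 2 / expected[use]))
    n_par = 2 * n_species + (1 if afterpulse else 0)
    dof = max(int(use.sum()) - n_par - 1, 1)
    return PCHFitResult(
        species=sp,
        reduced_chi2=chi2 / dof,
        log_likelihood=-best.fun,
        n_species=n_species,
        focus_correction=focus_correction,
        afterpulse_prob=ap,
    )
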