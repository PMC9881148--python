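"""Synthetic-data generators with known ground truth for every input class.

Every analysis stage in this package consumes tabular inputs (correlation
curves, titrations, photon-count histograms, nucleoside quantifications).
These generators produce all of them from known parameters, so each
generator/analyzer pair closes a round trip — the package's core test
surface.  All randomness flows from the seed in :class:`SimulationConfig`;
identical configs give bit-identical output.

Defaults mirror the experimental protocol the package targets: 12-step 1:1
dilution series starting at 5 µM protein over a fixed 10 nM labelled probe
(lowest non-zero concentration 5 µM / 2^12 ≈ 1.22 nM, plus a probe-only
blank), 40 µs photon-count bins over 300 s, log-spaced lag grids, terminal
labelling degrees of a few to a few tens of percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Sequence, Tuple, Union

import numpy as np

from .binding import TitrationSeries, binding_model_tau
from .composition import NucleosideCounts
from .correlation import CorrelationCurve, FocusGeometry, fit_g2, model_g2
from .errors import InvalidParameterError
from .pch import PCHistogram, SpeciesBrightness, pch_model
from .shape import MediumConditions, BOLTZMANN

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible scenario description shared by all generators.

    ``noise_sigma`` is the relative scale of multiplicative Gaussian noise
    (0 = noiseless); ``dilution_steps`` halvings from ``dilution_top`` define
    the titration grid; ``bin_time``/``duration`` size the photon-count
    histograms.
    """

    seed: int = 0
    noise_sigma: float = 0.0
    lag_min: float = 1e-6
    lag_max: float = 1.0
    n_lags: int = 100
    dilution_top: float = 5e-6  # mol/L
    dilution_steps: int = 12
    bin_time: float = 40e-6  # s
    duration: float = 300.0  # s

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if not (0 < self.lag_min < self.lag_max):
            raise InvalidParameterError("need 0 < lag_min < lag_max")
        if self.n_lags < 2 or self.dilution_steps < 1:
            raise InvalidParameterError("n_lags >= 2 and dilution_steps >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def lag_grid(self) -> np.ndarray:
        return np.geomspace(self.lag_min, self.lag_max, self.n_lags)

    @property
    def dilution_grid(self) -> np.ndarray:
        """Concentrations: top, ``dilution_steps`` halvings, then the blank."""
        nonzero = self.dilution_top / 2.0 ** np.arange(self.dilution_steps + 1)
        return np.concatenate([[0.0], nonzero[::-1]])  # ascending, blank first


def gen_correlation_curve(
    g0: float, tau_d: float, kappa: float, cfg: SimulationConfig = SimulationConfig()
) -> CorrelationCurve:
    """Model autocorrelation on the log lag grid plus multiplicative noise.

    The sd column is populated from the noise scale (heteroscedastic:
    proportional to the model value); with ``noise_sigma = 0`` the exact
    model values are returned and sd is omitted.
    """
    lags = cfg.lag_grid
    clean = model_g2(lags, g0, tau_d, kappa)
    if cfg.noise_sigma == 0:
        return CorrelationCurve(lags, clean, meta=f"synthetic seed={cfg.seed}")
    rng = cfg.rng()
    noisy = clean * (1.0 + cfg.noise_sigma * rng.standard_normal(lags.size))
    sd = cfg.noise_sigma * np.abs(clean)
    return CorrelationCurve(lags, noisy, sd=sd, meta=f"synthetic seed={cfg.seed}")


def _apparent_tau_correlation(f_bound, tau_free, tau_bound, kappa=5.0):
    """Apparent tau from a 1-component fit to a 2-component correlation.

    Quantifies the bias of the linear fraction-weighted convention against
    the true FCS observable (equal molecular brightness assumed, so species
    amplitudes are their number fractions).
    """
    lags = np.geomspace(1e-6, 1.0, 200)
    taus = np.empty_like(np.atleast_1d(f_bound), dtype=float)
    for i, fb in enumerate(np.atleast_1d(f_bound)):
        mix = (1 - fb) * model_g2(lags, 1.0, tau_free, kappa) + fb * model_g2(
            lags, 1.0, tau_bound, kappa
        )
        taus[i] = fit_g2(CorrelationCurve(lags, mix), kappa=kappa).tau_d
    return taus


def gen_titration(
    kd: float,
    tau_free: float,
    tau_bound: float,
    cfg: SimulationConfig = SimulationConfig(),
    probe_conc: float = 10e-9,
    convention: str = "linear",
) -> TitrationSeries:
    """Diffusion-time titration on the dilution grid, with known Kd.

    ``convention`` selects how the apparent tau of the free/bound mixture is
    formed: ``"linear"`` (fraction-weighted, matching the analysis model) or
    ``"correlation"`` (single-component fit to the two-component
    autocorrelation — the physically faithful observable).
    """
    if kd <= 0 or tau_bound <= tau_free:
        raise InvalidParameterError("kd > 0 and tau_bound > tau_free required")
    conc = cfg.dilution_grid
    if convention == "linear":
        clean = binding_model_tau(conc, kd, tau_free, tau_bound)
    elif convention == "correlation":
        f_bound = conc / (conc + kd)
        clean = _apparent_tau_correlation(f_bound, tau_free, tau_bound)
    else:
        raise InvalidParameterError("convention must be 'linear' or 'correlation'")
    rng = cfg.rng()
    if cfg.noise_sigma > 0:
        tau = clean * (1.0 + cfg.noise_sigma * rng.standard_normal(conc.size))
        sd = cfg.noise_sigma * clean
    else:
        tau = clean.copy()
        sd = None
    return TitrationSeries(
        concentrations=conc,
        tau_mean=tau,
        tau_sd=sd,
        probe_conc=probe_conc,
        meta=f"synthetic kd={kd:g} seed={cfg.seed}",
    )


def gen_pch(
    species: Sequence[SpeciesBrightness], cfg: SimulationConfig = SimulationConfig(),
    max_count: int = 64,
) -> PCHistogram:
    """Multinomial draw of duration/bin_time bins from the PCH model."""
    n_bins = int(round(cfg.duration / cfg.bin_time))
    probs = pch_model(species, max_count, truncation_tol=1e-4)
    probs = probs / probs.sum()
    freq = cfg.rng().multinomial(n_bins, probs)
    return PCHistogram(
        counts_axis=np.arange(max_count + 1),
        frequency=freq,
        bin_time=cfg.bin_time,
        duration=cfg.duration,
    )


def gen_labelled_complexes(
    P: int, L: float, n_complexes: int, cfg: SimulationConfig = SimulationConfig()
) -> np.ndarray:
    """Label counts of ``n_complexes`` independent complexes: Binomial(P, L).

    Empirical frequencies of {x = 1} and {x >= 2} converge to N1(P) and
    Nm(P); the empirical mean of x over x >= 2 draws converges to qm(P).
    """
    if P < 1 or not (0 <= L < 1) or n_complexes < 1:
        raise InvalidParameterError("require P >= 1, 0 <= L < 1, n_complexes >= 1")
    return cfg.rng().binomial(P, L, size=n_complexes)


LengthDist = Union[int, Sequence[int], Callable[[np.random.Generator, int], np.ndarray]]


def gen_branched_ensemble(
    n_molecules: int,
    length_dist: LengthDist,
    branch_prob: float,
    cfg: SimulationConfig = SimulationConfig(),
    max_rejections: int = 1000,
) -> Tuple[np.ndarray, NucleosideCounts]:
    """Random branched-polymer ensemble digested in silico to nucleosides.

    Each molecule draws a length ``n`` from ``length_dist`` (an int for fixed
    length, a sequence to sample from, or a callable ``f(rng, size)``) and a
    branch count ``b ~ Binomial(n - 1, branch_prob)`` (i.i.d. Bernoulli per
    internal linkage), rejected until ``n >= 2b + 1``.  Digestion bookkeeping
    is exact: each molecule contributes Ado = b+1, R2-Ado = b,
    R-Ado = n-2b-1.

    Returns the (n, b) array (shape ``(n_molecules, 2)``) and summed counts.
    Presets for the two polymerase variants this emulates: branch_prob 0.01
    (wildtype, ~1% branching) and 0.15 (hyperbranching mutant).
    """
    if not (0 <= branch_prob < 1):
        raise InvalidParameterError("branch_prob must lie in [0, 1)")
    if n_molecules < 1:
        raise InvalidParameterError("n_molecules must be >= 1")
    rng = cfg.rng()

    def draw_lengths(size: int) -> np.ndarray:
        if isinstance(length_dist, int):
            return np.full(size, length_dist)
        if callable(length_dist):
            return np.asarray(length_dist(rng, size), dtype=int)
        return rng.choice(np.asarray(length_dist, dtype=int), size=size)

    lengths = draw_lengths(n_molecules)
    if np.any(lengths < 1):
        raise InvalidParameterError("length_dist must be supported on n >= 1")
    branches = np.zeros(n_molecules, dtype=int)
    pending = np.arange(n_molecules)
    for _ in range(max_rejections):
        b = rng.binomial(np.maximum(lengths[pending] - 1, 0), branch_prob)
        ok = lengths[pending] >= 2 * b + 1
        branches[pending[ok]] = b[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise InvalidParameterError(
            f"branch_prob={branch_prob} infeasible for drawn lengths "
            f"({pending.size} molecules kept violating n >= 2b+1)"
        )
    counts = NucleosideCounts(
        ado=float(np.sum(branches + 1)),
        r_ado=float(np.sum(lengths - 2 * branches - 1)),
        r2_ado=float(np.sum(branches)),
    )
    return np.column_stack([lengths, branches]), counts


def gen_size_standards(
    masses_kda: Sequence[float],
    focus: FocusGeometry,
    medium: MediumConditions = MediumConditions(),
    density: float = 1350.0,
) -> List[Tuple[str, float, float]]:
    """Stokes-Einstein diffusion times for compact spheres of given masses.

    Emulates globular SEC size standards: radius from mass at protein density
    (kg/m^3), D from Stokes-Einstein, tau from the focus geometry.  Returns
    (name, mass_kDa, tau_s) tuples ready for the calibration fitter.
    """
    out = []
    for m in masses_kda:
        if m <= 0:
            raise InvalidParameterError("masses must be > 0")
        m_kg = m / AVOGADRO  # kDa = kg/mol, so kg per molecule = m / N_A
        r = (3.0 * m_kg / (4.0 * np.pi * density)) ** (1.0 / 3.0)
        d = BOLTZMANN * medium.temperature / (6.0 * np.pi * medium.viscosity * r)
        tau = focus.omega_xy**2 / (4.0 * d)
        out.append((f"std_{m:g}kDa", float(m), float(tau)))
    return out
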