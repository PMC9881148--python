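# Methods

This note documents the models implemented in `parfcs`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real measurements.

## Diffusion autocorrelation

The fit model is the standard single-component 3D-Gaussian-focus decay
g²(τ) = g₀/[(1 + τ/τ_d)(1 + τ/(τ_d κ²))^½]. Triplet and photophysics terms
are deliberately absent: fits are restricted to a lag window (default
0.1 ms – 1 s) chosen to exclude those fast processes, and the window is a
parameter because its justification is instrument-specific. The focus aspect
ratio κ follows the daily-calibration convention: fitted once on a
reference-dye curve (κ free), then held fixed for sample fits. Weighting is
1/sd² when per-lag uncertainties exist, unweighted otherwise.

Labelled concentrations come from the amplitude via c = 1/(g₀·V_eff·N_A)
with V_eff = π^{3/2}·ω³_xy·κ. No background correction is applied to g₀
(uncorrelated background inflates apparent concentration); efficiencies > 1
are reported as-is with a warning rather than clipped silently.

Units: seconds and metres inside the library; µs/nm/nM at the file and CLI
boundary, and cm²/s for diffusion coefficients, matching how these
quantities are conventionally reported.

## Prolate-ellipsoid shape inversion

The effective-radius form of Perrin's translational friction is implemented
exactly as displayed in the module docstring; T(H) = D_sphere/D_ellipsoid is
evaluated at equal volume (sphere radius a·H^⅓). Both printed formulas are
0/0 at H = 1, so below H = 1 + 10⁻⁶ the analytic sphere limit is returned;
the test suite checks continuity across the threshold. The inversion uses
Brent's method on log H over [1, 1000] — T is strictly increasing so the
root is unique and no tie-breaking is needed. Convergence is accepted at
10⁻¹⁰ relative agreement between T(H) and the requested ratio (the target
quantity is quoted to 2–3 significant figures, so this tolerance is
effectively exact). The implementation is validated to ~10⁻¹³ against the
closed-form Perrin factor F(q) = √(1−q²)/(q^{2/3} ln((1+√(1−q²))/q)),
q = 1/H, an algebraically independent route.

τ_calc — the sphere-equivalent diffusion time of a chain of known mass — is
treated as an *input* (from the mass calibration), not recomputed from first
principles: the empirical calibration absorbs the solvent shell, which no
ab-initio sphere model would capture.

## Mass calibration

A pure power law τ = α·M^β with no additive offset: τ ∝ r ∝ M^⅓ for compact
species, and the bundled sphere-equivalent diffusion times are consistent
with this form to r² > 0.999 (exponent 0.33). Synthetic Stokes–Einstein
standards (1.35 g/cm³ spheres at the calibrated focus) recover β = ⅓
exactly. The inverse M(τ) is documented as an upper bound on true mass for
anything non-spherical. Standards spanning less than a decade of mass warn
(exponent poorly constrained) but do not error, since narrow-range
calibrations are still useful for interpolation.

## Binding model

Two-state apparent-τ isotherm, τ(c) = τ_free + Δτ·c/(c + K_d), with total
protein ≈ free protein (probe fixed at 10 nM, protein up to 5 µM; the excess
approximation is marginal only at the very bottom of the dilution series).
The apparent τ of a free/bound mixture is modelled as the fraction-weighted
mean; the physically faithful observable is the brightness-weighted
correlation decay, and the generator can emit either convention
(`convention="correlation"` performs a single-component fit to the
two-component mixture curve) so the approximation bias is quantifiable
rather than hidden. Multi-phase binding curves are handled by explicit fit
windows isolating the first binding event, not by multi-site models.

A K_d is only *reported* when the data support it: the fit is flagged
estimable when (i) the fitted K_d ≤ c_max/4 — i.e. the model reaches ≥ 80%
of saturation at the highest fitted concentration — and (ii) the two-state
model actually describes the data (reduced χ² < 10 with uncertainties, or
< 5% maximal relative deviation without). A monotone rise that never
saturates therefore returns a not-estimable flag, not a number. Confidence
intervals are 95% profile-likelihood on K_d (the two τ parameters enter
linearly, so each profile point is a least-squares solve); simulated
coverage at 3% noise is ~94%.

Stoichiometry divides the calibration-derived mass excess of the complex by
the unit mass (e.g. 176 kDa for a tetramer of 44 kDa subunits). Because the
complex mass is an upper bound, the integer count is floored and reported as
an "at least" bound.

## Photon counting histogram

For particles Poisson-distributed in space with 3D Gaussian detection
profile B(r) and per-particle emission Poisson(q·B(r)), the count per bin is
compound-Poisson with cluster rates
χ_j = n/√(2π)·∫₀^∞ √t · Pois(j; q e^{−t}) dt (n = occupancy of the effective
volume π^{3/2}ω³κ; the mean count per bin is n·q·2^{−3/2}). The integral is
evaluated with the substitution t = u², which removes the √t endpoint
singularity; composite 24-panel, 24-node Gauss–Legendre quadrature then
reproduces the analytic first moment to machine precision. The distribution
follows from the Panjer recursion, which is exact on 0..max_count;
probability mass beyond the axis (> 10⁻⁶) raises rather than silently
renormalising. Independent species add their cluster rates (equivalent to
convolving their histograms). The construction was validated against a
direct Monte-Carlo simulation of particles in a box (maximum per-bin
z-score 2.1 over 40 000 draws) and against the analytic Poisson limit
q → 0 at fixed n·q.

Two optional single-scalar corrections, both off by default because their
reference parameterizations are instrument-specific: a first-order
out-of-focus shape correction (weight √t → √t(1 + F·t) in the cluster
integral) and afterpulsing (each detected count spawns one extra count with
fixed probability, k → k + Binomial(k, p)).

Fits are multinomial maximum likelihood (Nelder–Mead on log-parameters, two
starts for the two-species model); the reduced χ² on bins with appreciable
expected occupancy is reported for the one- vs two-species comparison. On
synthetic data with a 4:1 brightness ratio the one-species fit is worse by
two orders of magnitude; on true single-species data the second species
buys no improvement.

q_m(P) = Σ_{x≥2} x·N_x(P) is implemented verbatim as the probability-weighted
unconditional sum (equal to L·P − N₁), because the composition solver's
ratios are defined against it; the conditional per-complex mean q_m/N_m is
provided as a separately named variant. The integer solver minimises summed
squared log-error of (N₁/N_m, q_m/q₁) over P ≤ 100 with ties toward smaller
P; it is exact on noiseless forward data through P = 30 at labelling degrees
0.02–0.36 and recovers the modal P for P = 2–8 under 10% ratio noise. The
protein count per complex comes separately from the mass route
(`estimate_stoichiometry`), mirroring the two-source reasoning that
identifies the full complex composition.

## Branching metrics and the digestion convention

A molecule of n units with b branch points digests to Ado = b+1, R₂Ado = b,
RAdo = n−2b−1 (requiring n ≥ 2b+1, enforced in the generator by rejection).
This is the unique bookkeeping under which the displayed BR and APL formulas
are simultaneously the exact branch fraction and the exact mean chain
length; both identities are asserted exactly (not within tolerance) on
simulated ensembles. Whether input amounts are pmol or mole fractions is
irrelevant — both statistics are scale-invariant ratios.

## Synthetic generators: what they do and do not emulate

The generators reproduce the *protocol*: the dilution grid (5 µM, twelve 1:1
dilutions to 1.22 nM, probe-only blank), 40 µs bins over 300 s, terminal
labelling with at most one dye per chain, i.i.d. Bernoulli branching per
internal linkage. Noise is multiplicative Gaussian with a user-set relative
σ (correlation-curve noise in reality is lag-dependent per Koppel's variance
formula; that structure is not modelled, so weighted-fit performance on real
curves may differ). Detector dead time, afterpulse waveforms, background
photons and photobleaching are not simulated. Consequently the round-trip
tests demonstrate estimator correctness and calibration *under the stated
noise model*, not robustness to every instrumental artefact.

Default scenario parameters used in the test suite: τ_free = 431 µs,
τ_bound = 907 µs (a realistic free-chain/saturated-complex pair for a 50-mer
probe), 1% noise for single curves, 3% for titrations, K_d grid
{5, 8, 32, 99} nM spanning the nanomolar regime of strong PAR binders, 200
replicates for recovery/coverage statistics, 10⁶ draws for sampling checks,
and ensembles of 10–20 thousand molecules for the polymer metrics. These
sizes give sampling error comfortably below the asserted tolerances while
keeping the full suite under a minute of compute for the statistical parts.

## Known limitations

- Oblate ellipsoids, rotational diffusion and bead-model hydrodynamics are
  out of scope; H < 1 raises.
- The two-state binding model cannot represent cooperative, competitive or
  sequential multi-site binding; multi-phase curves must be windowed.
- Aggregation (non-monotone or unstable τ series) is not modelled; such
  series should be inspected before fitting.
- The PCH model assumes ideal 3D Gaussian detection up to the single
  first-order correction; strongly aberrated foci need a different profile.
- `mass_from_tau` is an upper bound for elongated species by construction;
  stoichiometries derived from it inherit that one-sidedness.
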