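# parfcs

Quantitative analysis of fluorescence correlation spectroscopy (FCS) and
photon counting histogram (PCH) experiments on poly(ADP-ribose) (PAR) and its
protein binders.

PAR is a nucleic-acid-like polymer of ADP-ribose units, optionally branched,
that hundreds of proteins read via dedicated binding motifs. FCS measures how
long a fluorescently labelled chain or complex dwells in a confocal focus
(its diffusion time τ_d), which reports its hydrodynamic size; PCH resolves
how many fluorophores diffuse together, which reports how many chains share a
complex. `parfcs` implements the full analysis chain between raw correlation
curves / count histograms and the biophysical quantities of interest —
aspect ratios, dissociation constants, stoichiometries, branching metrics —
for spectroscopists and biochemists working with PAR or comparable polymers.

## What it computes

**Autocorrelation fitting** (`parfcs.correlation`). Free 3D diffusion through
a Gaussian focus:

    g²(τ) = g₀ / [(1 + τ/τ_d)·√(1 + τ/(τ_d·κ²))]

with amplitude g₀, diffusion time τ_d and focus aspect ratio κ. The focus is
calibrated from a reference dye of known D via ω_xy = √(4·D·τ_d), after which
D = ω²_xy/(4τ_d) and the amplitude yields concentrations and labelling
efficiencies (g₀ = 1/(c·V_eff·N_A)).

**Prolate-ellipsoid shape inversion** (`parfcs.shape`). A chain that diffuses
slower than the equal-volume sphere predicted from its mass is modelled as a
prolate ellipsoid of aspect ratio H = b/a. The Perrin effective radii
r∥ᵉᶠᶠ(H), r⊥ᵉᶠᶠ(H) give D_ellipsoid = k_B·T·[1/(3f∥) + 2/(3f⊥)], and the
dimensionless shape factor T(H) = τ_ellipsoid/τ_sphere is inverted by
monotone root search, so a (τ_exp, τ_calc) pair maps to a unique H ≥ 1.

**Mass calibration** (`parfcs.calibration`). Globular size standards define
τ = α·M^β (β ≈ 1/3); the inverse gives an upper-bound mass for non-spherical
species.

**Binding analysis** (`parfcs.binding`). Titrations of a fixed 10 nM labelled
probe with protein produce diffusion-time binding curves fitted with the
two-state model τ(c) = τ_free + (τ_bound − τ_free)·c/(c + K_d), with
profile-likelihood confidence intervals, plateau-aware estimability flags
(no plateau → "N.D." rather than a number), onset detection, and
stoichiometry from the complex mass.

**PCH and labelling combinatorics** (`parfcs.pch`). The photon-count
distribution of Poisson-occupied species in a 3D Gaussian focus is computed
exactly as a compound Poisson (Panjer recursion over brightness-cluster
rates) and fitted by multinomial maximum likelihood for one or two brightness
species. Terminal labelling makes dye counts Binomial(P, L); the fractions
N₁(P), N_m(P) and weighted brightness q_m(P) invert the observed species
ratios to the integer number of chains per complex.

**Branching metrics** (`parfcs.composition`). From digestion nucleosides
(Ado = termini, R-Ado = linear units, R₂-Ado = branch points):

    BR [%] = R₂Ado/(Ado + RAdo + R₂Ado)·100,
    APL    = (Ado + RAdo + R₂Ado)/(Ado − R₂Ado)

both exact identities of the digestion bookkeeping.

**Synthetic data** (`parfcs.simulate`). Seeded generators for every input
class — noisy correlation curves, 12-step 1:1 dilution titrations (5 µM down
to 1.22 nM plus blank), 40 µs photon-count histograms, binomial labelling
draws, branched-polymer ensembles — so every analyzer closes a round trip
against known ground truth.

## Worked example

```bash
python examples/kd_titration.py
```

```
Kd = 33.2 nM (true 32), 95% CI [26.1, 42.5] nM
tau_free = 429 us, tau_bound = 908 us
onset of binding detected at 4.9 nM
complex mass <= 900 kDa  ->  at least 4 tetramers per chain (n = 5.0)
```

A simulated titration (Kd = 32 nM, 3% noise, the standard dilution grid) is
fitted back: the estimate lands within the confidence interval, the onset is
detected in the low-nanomolar range, and the saturated complex's apparent
mass (≈900 kDa via the τ = α·M^(1/3) calibration) corresponds to at least
four 176 kDa protein tetramers bound per 27 kDa chain — "at least" because
non-spherical complexes diffuse slower than spheres, making the mass an
upper bound and the count a lower bound.

The other example scripts cover the remaining capabilities: `fcs_fit.py`
(curve fitting, focus calibration, labelling efficiency),
`shape_inversion.py` (aspect ratios from the bundled diffusion-time table),
`pch_composition.py` (two-species photon statistics and chains-per-complex),
`par_branching.py` (BR/APL from in-silico digestion). A thin CLI mirrors
them: `parfcs simulate|fit-fcs|shape|calibrate|fit-kd|pch-fit|pch-compose|parstats`.

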